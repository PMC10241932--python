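import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, spearmanr

from fosnet.bwas import BWASResult, ContrastSpec, RegionFit
from fosnet.counts import ValidationError
from fosnet.network import (
    CorrelationResult,
    NoEdgesError,
    build_graph,
    estimate_pi0,
    fisher_exact_2x2,
    fisher_z_pvalue,
    mds_layout,
    network_fdr,
    select_significant_regions,
    select_threshold,
    spearman_matrix,
    tertile_connectivity,
)


def _corr(mat, regions, m=10):
    frame = pd.DataFrame(np.asarray(mat, float), index=regions, columns=regions)
    return CorrelationResult(frame, m)


def _bwas(pvals):
    fits = [
        RegionFit(f"R{i}", "ok", "", 0.1, 0.1, 2.0, 1.0, p, p, 1.1)
        for i, p in enumerate(pvals)
    ]
    return BWASResult(ContrastSpec("t", "c"), fits, ["intercept", "X"], 10)


class TestSelectSignificant:
    def test_none_significant_gives_empty(self):
        assert select_significant_regions(_bwas([0.2, 0.9])) == []

    def test_monotone_in_alpha(self):
        res = _bwas([0.01, 0.03, 0.2, 0.6])
        strict = select_significant_regions(res, 0.02)
        loose = select_significant_regions(res, 0.05)
        assert set(strict) <= set(loose)

    def test_failed_fits_excluded(self):
        res = _bwas([0.01])
        res.fits.append(RegionFit("bad", "fit-failed", "x", p=0.001))
        assert select_significant_regions(res) == ["R0"]


class TestSpearmanMatrix:
    def test_matches_scipy_oracle_on_toy(self, rng):
        frac = pd.DataFrame(
            rng.random((5, 3)), index=list("abcde"), columns=["r1", "r2", "r3"]
        )
        corr = spearman_matrix(frac, list("abcde"), ["r1", "r2", "r3"])
        oracle = spearmanr(frac.to_numpy()).statistic
        assert np.allclose(corr.rho.to_numpy(), oracle, atol=1e-12)
        assert np.allclose(np.diag(corr.rho), 1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        frac = pd.DataFrame(
            rng.random((6, 2)), index=list("abcdef"), columns=["r1", "r2"]
        )
        before = spearman_matrix(frac, list("abcdef"), ["r1", "r2"])
        frac["r1"] = np.exp(5 * frac["r1"])  # strictly increasing
        after = spearman_matrix(frac, list("abcdef"), ["r1", "r2"])
        pd.testing.assert_frame_equal(before.rho, after.rho)

    def test_constant_region_recorded_as_missing(self, rng):
        frac = pd.DataFrame(
            {"r1": rng.random(5), "flat": np.full(5, 0.3)}, index=list("abcde")
        )
        corr = spearman_matrix(frac, list("abcde"), ["r1", "flat"])
        assert np.isnan(corr.rho.loc["r1", "flat"])
        assert corr.rho.loc["flat", "flat"] == 1.0
        assert len(corr.pair_values()) == 0

    def test_too_few_animals_rejected(self, rng):
        frac = pd.DataFrame(rng.random((3, 2)), index=list("abc"),
                            columns=["r1", "r2"])
        with pytest.raises(ValidationError, match="Fisher"):
            spearman_matrix(frac, list("abc"), ["r1", "r2"])


class TestFisherZ:
    def test_zero_correlation_gives_p_one(self):
        assert fisher_z_pvalue(0.0, 22) == pytest.approx(1.0)

    def test_worked_value_rho_04_m22(self):
        # 2*normcdf(-atanh(0.4)*sqrt(19)) computed with an independent CDF call
        from scipy.stats import norm

        expected = 2 * norm.cdf(-np.arctanh(0.4) * np.sqrt(19))
        assert fisher_z_pvalue(0.4, 22) == pytest.approx(expected, rel=1e-12)
        assert fisher_z_pvalue(0.4, 22) == pytest.approx(0.065, abs=0.001)

    def test_strictly_decreasing_in_rho_and_m(self):
        assert fisher_z_pvalue(0.5, 10) < fisher_z_pvalue(0.4, 10)
        assert fisher_z_pvalue(0.4, 30) < fisher_z_pvalue(0.4, 10)
        assert fisher_z_pvalue(0.999999, 10) < 1e-8

    def test_small_m_rejected(self):
        with pytest.raises(ValidationError):
            fisher_z_pvalue(0.4, 3)


class TestPi0:
    def test_cap_rule(self):
        assert estimate_pi0([0.6, 0.7, 0.8, 0.9]) == 1.0

    def test_all_small_pvalues_give_zero(self):
        assert estimate_pi0([0.1, 0.2, 0.3]) == 0.0

    def test_uniform_null_near_one(self, rng):
        p = rng.random(10_000)
        assert estimate_pi0(p) == pytest.approx(1.0, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            estimate_pi0([])


class TestNetworkFdr:
    def test_plugin_values(self):
        assert network_fdr(0.05, 1.0, 3, 1) == pytest.approx(0.05)
        assert network_fdr(0.01, 0.5, 10, 9) == pytest.approx(0.02)

    def test_doubling_c_halves_fdr(self):
        assert network_fdr(0.02, 0.8, 12, 10) == pytest.approx(
            2 * network_fdr(0.02, 0.8, 12, 20)
        )

    def test_no_edges_signalled(self):
        with pytest.raises(NoEdgesError):
            network_fdr(0.05, 1.0, 5, 0)

    def test_all_pairs_variant(self):
        printed = network_fdr(0.05, 1.0, 10, 5, "printed")
        allp = network_fdr(0.05, 1.0, 10, 5, "all")
        assert allp / printed == pytest.approx(90 / 72)


def _strong_corr(k=6, m=22, rho=0.9):
    mat = np.full((k, k), rho)
    np.fill_diagonal(mat, 1.0)
    return _corr(mat, [f"R{i}" for i in range(k)], m)


class TestSelectThreshold:
    def test_floor_returned_when_fdr_already_met(self):
        sel = select_threshold(_strong_corr())
        assert sel.rho_threshold == 0.4
        assert not sel.empty and sel.fdr <= 0.05

    def test_null_data_raises_threshold_or_empties_graph(self, rng):
        x = rng.normal(size=(16, 20))
        frac = pd.DataFrame(x, index=[f"m{i}" for i in range(16)],
                            columns=[f"R{i}" for i in range(20)])
        corr = spearman_matrix(frac, list(frac.index), list(frac.columns))
        sel = select_threshold(corr)
        assert sel.empty or sel.rho_threshold > 0.4

    def test_lowering_target_never_lowers_threshold(self, rng):
        x = rng.normal(size=(12, 10))
        frac = pd.DataFrame(x, index=[f"m{i}" for i in range(12)],
                            columns=[f"R{i}" for i in range(10)])
        corr = spearman_matrix(frac, list(frac.index), list(frac.columns))
        loose = select_threshold(corr, target_fdr=0.5)
        strict = select_threshold(corr, target_fdr=0.05)
        assert strict.rho_threshold >= loose.rho_threshold


class TestBuildGraph:
    def test_no_edges_above_max(self):
        corr = _strong_corr(rho=0.3)
        sel = select_threshold(corr)
        graph = build_graph(corr, sel)
        assert graph.graph.number_of_edges() == 0

    def test_edge_count_matches_selection(self):
        corr = _strong_corr()
        sel = select_threshold(corr)
        graph = build_graph(corr, sel)
        assert graph.graph.number_of_edges() == sel.n_edges

    def test_four_region_toy_edge_set(self):
        mat = np.eye(4)
        vals = {(0, 1): 0.9, (0, 2): -0.5, (0, 3): 0.1, (1, 2): 0.2,
                (1, 3): 0.05, (2, 3): 0.45}
        for (i, j), v in vals.items():
            mat[i, j] = mat[j, i] = v
        corr = _corr(mat, list("ABCD"), m=30)
        sel = select_threshold(corr, target_fdr=1.0)  # keep the floor 0.4
        graph = build_graph(corr, sel)
        edges = {frozenset(e[:2]) for e in graph.edges}
        assert edges == {frozenset("AB"), frozenset("AC"), frozenset("CD")}

    def test_edge_set_invariant_to_region_order(self, rng):
        x = rng.normal(size=(8, 5))
        regions = [f"R{i}" for i in range(5)]
        frac = pd.DataFrame(x, index=[f"m{i}" for i in range(8)], columns=regions)
        g1 = build_graph(*(lambda c: (c, select_threshold(c, 1.0)))(
            spearman_matrix(frac, list(frac.index), regions)))
        g2 = build_graph(*(lambda c: (c, select_threshold(c, 1.0)))(
            spearman_matrix(frac, list(frac.index), regions[::-1])))
        e1 = {frozenset(e[:2]) for e in g1.edges}
        e2 = {frozenset(e[:2]) for e in g2.edges}
        assert e1 == e2


class TestMdsLayout:
    def test_output_shape(self):
        layout = mds_layout(_strong_corr(k=5))
        assert layout.shape == (5, 2)

    def test_correlated_pair_plots_closer(self):
        mat = np.eye(3)
        mat[0, 1] = mat[1, 0] = 0.9
        corr = _corr(mat, list("ABC"))
        layout = mds_layout(corr)
        d = lambda a, b: np.hypot(*(layout.loc[a] - layout.loc[b]))  # noqa: E731
        assert d("A", "B") < d("A", "C")

    def test_embedded_distances_track_dissimilarity(self, rng):
        for _ in range(5):
            x = rng.normal(size=(10, 6))
            frac = pd.DataFrame(x, index=[f"m{i}" for i in range(10)],
                                columns=[f"R{i}" for i in range(6)])
            corr = spearman_matrix(frac, list(frac.index), list(frac.columns))
            layout = mds_layout(corr).to_numpy()
            diff = layout[:, None, :] - layout[None, :, :]
            emb = np.sqrt((diff**2).sum(-1))
            dis = 1 - corr.rho.to_numpy()
            iu = np.triu_indices(6, 1)
            r = spearmanr(emb[iu], dis[iu]).statistic
            assert r > 0.5


class TestTertileConnectivity:
    def test_counts_match_bruteforce(self, rng):
        frac = pd.DataFrame(rng.random((20, 9)),
                            index=[f"m{i}" for i in range(20)],
                            columns=[f"R{i}" for i in range(9)])
        tert = {"low": ["R0", "R1", "R2"], "medium": ["R3", "R4", "R5"],
                "high": ["R6", "R7", "R8"]}
        out = tertile_connectivity(frac, tert, rho_threshold=0.2)
        for name, regions in tert.items():
            rho = spearmanr(frac[regions].to_numpy()).statistic
            iu = np.triu_indices(3, 1)
            expected = int((np.abs(rho[iu]) >= 0.2).sum())
            assert out.loc[name, "connected"] == expected
            assert out.loc[name, "total"] == 3
            assert out.loc[name, "percent"] == pytest.approx(
                100 * expected / 3
            )

    def test_small_tertile_rejected(self, rng):
        frac = pd.DataFrame(rng.random((5, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValidationError):
            tertile_connectivity(frac, {"low": ["a"]})


class TestFisherExact:
    def test_published_style_table(self):
        # medium-vs-low connected pair counts: 46/279 vs 22/329
        assert fisher_exact_2x2(46, 279, 22, 329) == pytest.approx(8e-4, abs=5e-5)

    def test_identical_rows_give_one(self):
        assert fisher_exact_2x2(5, 10, 5, 10) == 1.0

    def test_tiny_table_enumeration(self):
        assert fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(0, 0, 3, 4)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_matches_scipy_oracle(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12
        )
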
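"""Functional-network inference from correlated c-Fos variation.

Within one experimental group of M animals, normalized regional counts are
rank-correlated between every pair of regions (Spearman rho).  A pair is
drawn as a network edge when |rho| exceeds a threshold, which starts at a
floor rho_min = 0.4 and is raised just enough to bring the estimated false
discovery rate of the edge set under a target (default 0.05).  The estimate
combines the Fisher z-transformation p-value at the threshold,

    P = 2 * normcdf(-atanh(rho_threshold) * sqrt(M - 3)),

a Storey-type estimate of the null proportion pi0 at lambda = 0.5, and the
edge count C:

    FDR = P_threshold * pi0 * (k - 1) * (k - 2) / (2 * C),

with k the number of regions entering the comparison.  The (k-1)(k-2)/2
pair count is used as printed in the procedure's definition; ``pair_count=
"all"`` switches to k(k-1)/2 (the number of distinct pairs) for sensitivity
analysis.  Graphs are laid out by classical multidimensional scaling of the
dissimilarity d = 1 - rho, so strongly correlated regions plot close
together, deterministically (eigendecomposition, no stochastic stress
minimization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm

from .counts import ValidationError
from .bwas import BWASResult

logger = logging.getLogger(__name__)


class NoEdgesError(ValueError):
    """FDR is undefined when no pair exceeds the candidate threshold."""


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: pd.DataFrame           # k x k, symmetric, unit diagonal, NaN = undefined
    n_animals: int              # M

    @property
    def regions(self) -> list[str]:
        return list(self.rho.index)

    def pair_values(self) -> pd.Series:
        """Upper-triangle |defined| correlations indexed by (region, region)."""
        k = len(self.rho)
        iu = np.triu_indices(k, 1)
        vals = self.rho.to_numpy()[iu]
        idx = pd.MultiIndex.from_arrays(
            [self.rho.index[iu[0]], self.rho.columns[iu[1]]]
        )
        return pd.Series(vals, index=idx).dropna()


def select_significant_regions(result: BWASResult, alpha: float = 0.05) -> list[str]:
    """Regions with a successful fit and unadjusted p < alpha (monotone in alpha)."""
    return [f.region for f in result.ok_fits if f.p < alpha]


def spearman_matrix(
    fractions: pd.DataFrame, animals: list[str], regions: list[str]
) -> CorrelationResult:
    """Pairwise Spearman rho (average ranks for ties) over a group's animals.

    Regions with zero rank variance across the group have no defined
    correlation; their off-diagonal entries are NaN and are excluded from
    edge counting downstream.
    """
    if len(animals) < 4:
        raise ValidationError(
            f"need >= 4 animals for the Fisher z-transformation, got {len(animals)}"
        )
    if len(regions) < 2:
        raise ValidationError("need >= 2 regions")
    sub = fractions.loc[animals, regions]
    ranks = sub.rank(axis=0, method="average").to_numpy(float)
    centered = ranks - ranks.mean(axis=0)
    sd = centered.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        standardized = centered / sd
        rho = (standardized.T @ standardized) / len(animals)
    rho[np.abs(sd) < 1e-12, :] = np.nan
    rho[:, np.abs(sd) < 1e-12] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0, out=rho)
    frame = pd.DataFrame(rho, index=regions, columns=regions)
    return CorrelationResult(frame, len(animals))


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------


def fisher_z_pvalue(rho, n_animals: int):
    """Two-tailed P = 2*normcdf(-atanh(|rho|)*sqrt(M-3)); needs M >= 4."""
    if n_animals <= 3:
        raise ValidationError("Fisher z-transformation requires M >= 4 animals")
    rho_arr = np.asarray(rho, float)
    if np.any(np.abs(rho_arr) >= 1.0):
        raise ValidationError("|rho| must be < 1 for the Fisher z-transformation")
    p = 2.0 * norm.cdf(-np.abs(np.arctanh(rho_arr)) * np.sqrt(n_animals - 3))
    return float(p) if np.isscalar(rho) else p


def estimate_pi0(p, lam: float = 0.5) -> float:
    """Storey estimate of the null proportion: #{p > lambda}/((1-lambda) m), capped."""
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0.0 < lam < 1.0:
        raise ValidationError("lambda must lie in (0, 1)")
    return float(np.clip((p > lam).sum() / ((1.0 - lam) * p.size), 0.0, 1.0))


def network_fdr(
    p_threshold: float, pi0: float, k: int, c: int, pair_count: str = "printed"
) -> float:
    """FDR = P_threshold * pi0 * (k-1)(k-2) / (2C), evaluated verbatim.

    ``pair_count="all"`` substitutes k(k-1)/2 distinct pairs instead.
    """
    if k < 3:
        raise ValidationError("need k >= 3 regions")
    if c < 1:
        raise NoEdgesError("no supra-threshold pairs: FDR undefined")
    pairs = (k - 1) * (k - 2) / 2.0 if pair_count == "printed" else k * (k - 1) / 2.0
    return float(p_threshold * pi0 * pairs / c)


@dataclass
class ThresholdSelection:
    rho_threshold: float
    p_threshold: float
    pi0: float
    n_edges: int                # C
    fdr: float                  # achieved estimate (NaN when empty)
    target_fdr: float
    rho_min: float
    k: int
    n_pairs_defined: int
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "rho_threshold": self.rho_threshold,
            "p_threshold": self.p_threshold,
            "pi0": self.pi0,
            "n_edges": self.n_edges,
            "fdr": self.fdr,
            "target_fdr": self.target_fdr,
            "rho_min": self.rho_min,
            "k": self.k,
            "n_pairs_defined": self.n_pairs_defined,
            "empty": self.empty,
        }


def select_threshold(
    corr: CorrelationResult,
    target_fdr: float = 0.05,
    rho_min: float = 0.4,
    pair_count: str = "printed",
) -> ThresholdSelection:
    """Smallest |rho| threshold >= rho_min whose estimated FDR meets the target.

    pi0 is estimated once from the Fisher-z p-values of all defined pairs
    (lambda = 0.5).  Candidates are rho_min itself followed by the sorted
    observed |rho| values above it; if the floor already satisfies the
    target the floor is returned exactly.  When no candidate passes (or no
    pair reaches the floor) an empty-graph selection is returned, flagged.
    """
    pairs = corr.pair_values()
    absr = np.abs(pairs.to_numpy())
    k, m = len(corr.rho), corr.n_animals
    if absr.size == 0:
        raise ValidationError("no defined region pairs")
    pvals = fisher_z_pvalue(np.clip(absr, 0, 1 - 1e-12), m)
    pi0 = estimate_pi0(pvals)

    candidates = [rho_min] + sorted(v for v in np.unique(absr) if v > rho_min)
    last_fdr = np.nan
    for t in candidates:
        c = int((absr >= t - 1e-12).sum())
        if c == 0:
            break
        p_thr = fisher_z_pvalue(min(t, 1 - 1e-12), m)
        fdr = network_fdr(p_thr, pi0, k, c, pair_count)
        last_fdr = fdr
        if fdr <= target_fdr:
            return ThresholdSelection(
                float(t), p_thr, pi0, c, fdr, target_fdr, rho_min, k, absr.size
            )
    logger.warning("select_threshold: no threshold met FDR %.3g; empty graph",
                   target_fdr)
    return ThresholdSelection(
        np.inf, np.nan, pi0, 0, last_fdr, target_fdr, rho_min, k, absr.size,
        empty=True,
    )


# ---------------------------------------------------------------------------
# graph construction and layout
# ---------------------------------------------------------------------------


@dataclass
class NetworkGraph:
    graph: nx.Graph
    selection: ThresholdSelection

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["rho"]) for u, v, d in self.graph.edges(data=True)]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["region_a", "region_b", "rho"])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_graph(
    corr: CorrelationResult,
    selection: ThresholdSelection,
    divisions: dict[str, str] | None = None,
) -> NetworkGraph:
    """Edges between distinct regions with |rho| >= the selected threshold.

    The signed correlation is kept on each edge; nodes carry their
    anatomical division tag when a mapping is supplied.
    """
    g = nx.Graph()
    divisions = divisions or {}
    for r in corr.regions:
        g.add_node(r, division=divisions.get(r, "unknown"))
    if not selection.empty:
        for (a, b), r in corr.pair_values().items():
            if abs(r) >= selection.rho_threshold - 1e-12:
                g.add_edge(a, b, rho=float(r))
    return NetworkGraph(g, selection)


def mds_layout(corr: CorrelationResult) -> pd.DataFrame:
    """Classical MDS of d = 1 - rho into the plane; deterministic.

    Undefined correlations are imputed as rho = 0 (d = 1) with a warning.
    Axis signs are fixed so the largest-magnitude coordinate on each axis is
    positive, making the layout invariant to eigensolver sign conventions.
    """
    k = len(corr.rho)
    if k < 3:
        raise ValidationError("MDS layout needs >= 3 regions")
    rho = corr.rho.to_numpy(float).copy()
    if np.isnan(rho).any():
        logger.warning("mds_layout: imputing %d undefined correlations as 0",
                       int(np.isnan(rho).sum()))
        rho = np.nan_to_num(rho, nan=0.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d2 = d**2
    j = np.eye(k) - np.full((k, k), 1.0 / k)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    for axis in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, axis]))
        if coords[i, axis] < 0:
            coords[:, axis] *= -1.0
    return pd.DataFrame(coords, index=corr.regions, columns=["x", "y"])


# ---------------------------------------------------------------------------
# expression-tertile connectivity and Fisher exact test
# ---------------------------------------------------------------------------


def tertile_connectivity(
    fractions: pd.DataFrame,
    tertiles: dict[str, list[str]],
    rho_threshold: float = 0.4,
) -> pd.DataFrame:
    """Within-tertile connected-pair counts over the pooled animal cohort.

    For each expression tertile, counts the pairs of member regions whose
    pooled-cohort |Spearman rho| meets the edge rule; pairs with undefined
    correlation are excluded from both counts and totals.
    """
    rows = {}
    animals = list(fractions.index)
    for name, regions in tertiles.items():
        usable = [r for r in regions if r in fractions.columns]
        if len(usable) < 2:
            raise ValidationError(f"tertile {name!r} has < 2 usable regions")
        corr = spearman_matrix(fractions, animals, usable)
        vals = corr.pair_values()
        total = len(vals)
        connected = int((np.abs(vals.to_numpy()) >= rho_threshold - 1e-12).sum())
        rows[name] = {
            "connected": connected,
            "total": total,
            "percent": 100.0 * connected / total if total else np.nan,
        }
    return pd.DataFrame(rows).T[["connected", "total", "percent"]]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric point probabilities (margins fixed) over all tables
    whose probability does not exceed that of the observed table (with a
    1 + 1e-7 relative tolerance against ties lost to rounding, as in
    standard implementations).
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValidationError("cell counts must be nonnegative integers")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if min(row1, c + d, col1, b + d) <= 0:
        raise ValidationError("all margins must be positive")
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))
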
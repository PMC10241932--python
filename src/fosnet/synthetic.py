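"""Synthetic study generator: count tables, correlated cohorts, ethograms.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without the study's imaging or video data:

* region counts drawn negative-binomially around animal-specific totals
  T_i (log-normal, then conditioned on via the ln-offset), with planted
  log-fold treatment effects, batch offsets and an optional bridge group;
* inter-region correlation induced by per-animal latent factors that
  multiply region rates through configurable loadings;
* Markov-chain ethograms with day-dependent change-only transition
  matrices, geometric (or negative-binomial) dwell times, state-dependent
  gamma velocities and an integrated 2-D centroid path.

Every generator draws from named, spawned random substreams -- one per
group or component -- so adding a group never perturbs another group's
data, and identical seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ethogram as eth
from .bwas import ContrastSpec
from .counts import AnimalMeta, CountTable, synthetic_region_names

__all__ = [
    "GroupSpec", "StudyDesign", "EffectSpec", "LatentNetworkSpec",
    "BehaviorSpec", "ConfigError", "simulate_counts",
    "simulate_correlated_counts", "simulate_ethogram", "simulate_study",
    "default_study_config", "default_behavior_spec", "StudyBundle",
]


class ConfigError(ValueError):
    """Raised with a list of all violations found in a configuration."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_animals: int
    batch: str
    treatment: int = 0          # X
    bridge: int = 0             # A


@dataclass
class StudyDesign:
    """Cohort layout plus the law for per-animal totals.

    ``total_count_law`` gives (mean-log, sd-log) of the log-normal total
    count T_i; defaults produce brain totals around 6e4 with the strong
    animal-to-animal variability that motivates the offset model.
    """

    groups: list[GroupSpec]
    batches: list[str]
    n_regions: int
    total_count_law: tuple[float, float] = (11.0, 0.4)
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        problems = []
        if not self.groups:
            problems.append("design has no groups")
        for g in self.groups:
            if g.n_animals < 1:
                problems.append(f"group {g.label!r}: n_animals must be >= 1")
            if g.batch not in self.batches:
                problems.append(
                    f"group {g.label!r}: batch {g.batch!r} not in batches"
                )
        if self.n_regions < 1:
            problems.append("n_regions must be >= 1")
        if self.total_count_law[1] < 0:
            problems.append("total_count_law sd-log must be >= 0")
        if self.region_names is not None and len(self.region_names) != self.n_regions:
            problems.append("region_names length differs from n_regions")
        if problems:
            raise ConfigError("; ".join(problems))
        if self.region_names is None:
            self.region_names = synthetic_region_names(self.n_regions)


@dataclass
class EffectSpec:
    """Per-region coefficients of the generating NB model (log scale)."""

    baseline_log_rate: np.ndarray     # beta0
    treatment_log_fc: np.ndarray      # beta1
    batch_log_fc: np.ndarray          # beta2 (applied when batch == batches[0])
    bridge_log_fc: np.ndarray         # beta3
    dispersion: np.ndarray            # phi > 0

    def __post_init__(self) -> None:
        fields_ = {
            "baseline_log_rate": self.baseline_log_rate,
            "treatment_log_fc": self.treatment_log_fc,
            "batch_log_fc": self.batch_log_fc,
            "bridge_log_fc": self.bridge_log_fc,
            "dispersion": self.dispersion,
        }
        n = None
        problems = []
        for name, v in fields_.items():
            arr = np.asarray(v, float)
            setattr(self, name, arr)
            if arr.ndim != 1:
                problems.append(f"{name} must be one-dimensional")
            if n is None:
                n = arr.size
            elif arr.size != n:
                problems.append(f"{name} has length {arr.size}, expected {n}")
        if np.any(self.dispersion <= 0):
            problems.append("dispersion values must all be > 0")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def n_regions(self) -> int:
        return self.baseline_log_rate.size

    @classmethod
    def null(cls, n_regions: int, dispersion: float = 2.0) -> "EffectSpec":
        """No treatment/batch/bridge effects; deterministic graded baselines.

        Baselines are log proportions spanning two orders of magnitude and
        normalized to sum to one, so region means are T_i-proportional.
        """
        w = np.geomspace(1.0, 100.0, n_regions)
        return cls(
            np.log(w / w.sum()),
            np.zeros(n_regions),
            np.zeros(n_regions),
            np.zeros(n_regions),
            np.full(n_regions, float(dispersion)),
        )

    def with_planted(self, n_planted: int, log_fc: float = 1.0) -> "EffectSpec":
        """Plant alternating-sign treatment effects in the first regions."""
        if not 0 < n_planted <= self.n_regions:
            raise ConfigError("n_planted must be in [1, n_regions]")
        b1 = np.zeros(self.n_regions)
        signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
        b1[:n_planted] = signs * abs(log_fc)
        return replace(self, treatment_log_fc=b1)


@dataclass
class LatentNetworkSpec:
    """Latent-factor model inducing inter-region rank correlation.

    Each animal draws factor scores f ~ N(0, factor_scale^2 I) and
    idiosyncratic noise e_j ~ N(0, idio_scale^2); region rates are
    multiplied by exp(loadings @ f + e), so regions sharing loadings
    co-vary across animals.
    """

    loadings: np.ndarray              # n_regions x n_factors
    factor_scale: float = 1.0
    idiosyncratic_scale: float = 0.0

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, float))

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


@dataclass
class BehaviorSpec:
    """Semi-Markov ethogram generator parameters.

    ``transitions`` maps a day label to a change-only transition matrix
    (zero diagonal, stochastic rows) over the six-state alphabet; dwell
    times are geometric by default (pure Markov in the jump chain) with an
    optional negative-binomial law for smoother, filtered-looking bouts;
    velocities are gamma with state-specific means (pixels/frame).
    """

    transitions: dict[str, pd.DataFrame]
    dwell_mean: dict[str, float]
    velocity_mean: dict[str, float]
    states: tuple[str, ...] = eth.STATES6
    dwell_law: str = "geometric"         # or "nbinom"
    dwell_shape: float = 2.0
    velocity_shape: float = 2.0
    frame_rate: float = eth.DEFAULT_FRAME_RATE
    arena: tuple[float, float] = (400.0, 400.0)
    heading_sigma: float = 0.3

    def __post_init__(self) -> None:
        problems = []
        for day, tm in self.transitions.items():
            m = tm.to_numpy(float)
            if list(tm.index) != list(self.states) or list(tm.columns) != list(
                self.states
            ):
                problems.append(f"day {day!r}: matrix not indexed by the states")
                continue
            if np.any(np.abs(np.diag(m)) > 1e-12):
                problems.append(f"day {day!r}: transition diagonal must be zero")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-8):
                problems.append(f"day {day!r}: rows must sum to 1")
            if np.any(m < 0):
                problems.append(f"day {day!r}: negative transition probability")
        for s in self.states:
            if self.dwell_mean.get(s, 0) < 1:
                problems.append(f"state {s!r}: dwell mean must be >= 1 frame")
            if self.velocity_mean.get(s, -1) < 0:
                problems.append(f"state {s!r}: velocity mean must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def _group_streams(seed: int, n_groups: int, n_sub: int):
    root = np.random.SeedSequence(seed)
    return [child.spawn(n_sub) for child in root.spawn(n_groups)]


def simulate_counts(
    design: StudyDesign, effects: EffectSpec, seed: int
) -> tuple[CountTable, AnimalMeta]:
    """Draw Y_ij ~ NB(mu_ij, phi_j), mu_ij = exp(eta_j(group)) * T_i."""
    return _simulate(design, effects, None, seed)


def simulate_correlated_counts(
    design: StudyDesign, effects: EffectSpec, net: LatentNetworkSpec, seed: int
) -> tuple[CountTable, AnimalMeta]:
    """As :func:`simulate_counts`, with latent-factor rate multipliers."""
    if net.loadings.shape[0] != design.n_regions:
        raise ConfigError(
            f"loadings: {net.loadings.shape[0]} rows, expected "
            f"n_regions={design.n_regions}"
        )
    return _simulate(design, effects, net, seed)


def _simulate(design, effects, net, seed):
    if effects.n_regions != design.n_regions:
        raise ConfigError(
            f"effects: length {effects.n_regions}, expected "
            f"n_regions={design.n_regions}"
        )
    mean_log, sd_log = design.total_count_law
    streams = _group_streams(seed, len(design.groups), 3)
    rows, totals, meta_rows, ids = [], [], [], []
    for g, (s_total, s_count, s_factor) in zip(design.groups, streams):
        rng_t = np.random.default_rng(s_total)
        rng_y = np.random.default_rng(s_count)
        rng_f = np.random.default_rng(s_factor)
        t = np.maximum(1, np.round(rng_t.lognormal(mean_log, sd_log, g.n_animals)))
        z = 1.0 if g.batch == design.batches[0] else 0.0
        eta = (
            effects.baseline_log_rate
            + g.treatment * effects.treatment_log_fc
            + z * effects.batch_log_fc
            + g.bridge * effects.bridge_log_fc
        )
        mu = t[:, None] * np.exp(eta)[None, :]
        if net is not None:
            f = rng_f.normal(0.0, net.factor_scale, (g.n_animals, net.n_factors))
            e = rng_f.normal(
                0.0, net.idiosyncratic_scale, (g.n_animals, design.n_regions)
            )
            mu = mu * np.exp(f @ net.loadings.T + e)
        phi = effects.dispersion[None, :]
        y = rng_y.negative_binomial(phi, phi / (phi + mu))
        rows.append(y)
        totals.append(t)
        for i in range(g.n_animals):
            ids.append(f"{g.label}-{i + 1:02d}")
            meta_rows.append((g.label, g.batch))
    counts = pd.DataFrame(
        np.vstack(rows), index=ids, columns=design.region_names
    )
    counts.index.name = "animal_id"
    meta = pd.DataFrame(meta_rows, index=ids, columns=["group", "batch"])
    meta.index.name = "animal_id"
    table = CountTable(
        counts, totals=pd.Series(np.concatenate(totals), index=ids),
        totals_from="column",
    )
    return table, AnimalMeta(meta)


# ---------------------------------------------------------------------------
# ethogram simulation
# ---------------------------------------------------------------------------


def simulate_ethogram(
    spec: BehaviorSpec, n_frames: int, day: str, seed: int,
    animal: str = "", group: str = "",
) -> eth.Ethogram:
    """Semi-Markov state sequence with velocities and a centroid path."""
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    if day not in spec.transitions:
        raise ConfigError(
            f"unknown day {day!r}; known: {sorted(spec.transitions)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tm = spec.transitions[day].to_numpy(float)
    states = list(spec.states)
    s = rng.integers(len(states))
    labels = np.empty(n_frames, dtype=object)
    velocity = np.empty(n_frames)
    pos = 0
    while pos < n_frames:
        mean_d = spec.dwell_mean[states[s]]
        if spec.dwell_law == "geometric":
            dwell = int(rng.geometric(1.0 / mean_d))
        else:  # negative-binomial dwell: smoother, overdispersed bouts
            shape = spec.dwell_shape
            p = shape / (shape + mean_d - 1.0)
            dwell = 1 + int(rng.negative_binomial(shape, p))
        dwell = min(dwell, n_frames - pos)
        labels[pos:pos + dwell] = states[s]
        vm = spec.velocity_mean[states[s]]
        if vm > 0:
            velocity[pos:pos + dwell] = rng.gamma(
                spec.velocity_shape, vm / spec.velocity_shape, dwell
            )
        else:
            velocity[pos:pos + dwell] = 0.0
        pos += dwell
        s = rng.choice(len(states), p=tm[s])
    theta = np.cumsum(rng.normal(0.0, spec.heading_sigma, n_frames))
    w, h = spec.arena
    x = _reflect(w / 2 + np.cumsum(velocity * np.cos(theta)), w)
    y = _reflect(h / 2 + np.cumsum(velocity * np.sin(theta)), h)
    return eth.Ethogram(labels, x, y, velocity, spec.frame_rate, day, animal,
                        group, spec.states)


def _reflect(pos: np.ndarray, size: float) -> np.ndarray:
    r = np.mod(pos, 2.0 * size)
    return np.where(r > size, 2.0 * size - r, r)


def default_behavior_spec(day2_bias: float = 0.2) -> BehaviorSpec:
    """Two-day behavior spec with a planted habituation shift on day 2.

    Day-1 transitions are uniform over the other five states.  On day 2 a
    fraction ``day2_bias`` of each row's mass is redirected toward the
    states less active than the source (per ``ethogram.ACTIVITY_ORDER``),
    emulating habituation: transitions increasingly favor quieter states.
    """
    states = list(eth.STATES6)
    k = len(states)
    day1 = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(day1, 0.0)
    rank = {s: i for i, s in enumerate(eth.ACTIVITY_ORDER)}
    day2 = day1.copy()
    for i, s in enumerate(states):
        lower = [j for j, t in enumerate(states) if rank[t] < rank[s]]
        if not lower:
            continue
        day2[i] = day1[i] * (1.0 - day2_bias)
        day2[i, lower] += day2_bias / len(lower)
    mk = lambda m: pd.DataFrame(m, index=states, columns=states)  # noqa: E731
    return BehaviorSpec(
        transitions={"day1": mk(day1), "day2": mk(day2)},
        dwell_mean={
            "slow_explore": 30, "grooming": 40, "fast_explore": 20,
            "reared": 25, "turning_walk": 15, "locomotion": 50,
        },
        velocity_mean={
            "slow_explore": 0.8, "grooming": 0.2, "fast_explore": 2.0,
            "reared": 0.3, "turning_walk": 2.5, "locomotion": 5.0,
        },
    )


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


def default_study_config() -> dict:
    """Default study layout mirroring the cohort sizes of the source design.

    One single-batch contrast (treatment n=16 vs control n=22, the
    perturbation-vs-control sizes) with 20 planted |log FC| = 1 effects
    among 60 regions, and a two-group, two-day behavioral arm in which the
    control group habituates strongly (day-2 transition bias 0.2) while the
    perturbed group barely does (0.02).
    """
    return {
        "counts": {
            "n_regions": 60,
            "dispersion": 2.0,
            "total_count_law": [11.0, 0.4],
            "contrasts": {
                "perturbation_vs_control": {
                    "treatment": {"label": "perturbed", "n": 16, "batch": "b1"},
                    "control": {"label": "control", "n": 22, "batch": "b1"},
                    "planted": {"n_regions": 20, "log_fc": 1.0},
                },
            },
        },
        "behavior": {
            "groups": {"control": 12, "perturbed": 10},
            "days": ["day1", "day2"],
            "n_frames": 24000,
            "day2_bias": {"control": 0.2, "perturbed": 0.02},
        },
    }


@dataclass
class SimulatedContrast:
    table: CountTable
    meta: AnimalMeta
    contrast: ContrastSpec
    effects: EffectSpec


@dataclass
class StudyBundle:
    contrasts: dict[str, SimulatedContrast]
    ethograms: dict[str, dict[str, list[eth.Ethogram]]]  # group -> day -> animals
    seed: int
    seed_log: dict = field(default_factory=dict)


def _validate_study_config(config: dict) -> list[str]:
    problems = []
    counts = config.get("counts")
    if not isinstance(counts, dict):
        problems.append("missing 'counts' section")
    else:
        if counts.get("n_regions", 0) < 1:
            problems.append("counts.n_regions must be >= 1")
        contrasts = counts.get("contrasts")
        if not contrasts:
            problems.append("counts.contrasts must name at least one contrast")
        else:
            for name, spec in contrasts.items():
                for side in ("treatment", "control"):
                    part = spec.get(side)
                    if not part or part.get("n", 0) < 1:
                        problems.append(
                            f"contrast {name!r}: {side} needs a positive n"
                        )
                planted = spec.get("planted", {})
                if planted and not (
                    0 < planted.get("n_regions", 0) <= counts.get("n_regions", 0)
                ):
                    problems.append(
                        f"contrast {name!r}: planted.n_regions outside "
                        f"[1, n_regions]"
                    )
    behavior = config.get("behavior")
    if behavior is not None:
        if not behavior.get("groups"):
            problems.append("behavior.groups must be nonempty")
        for g, n in (behavior.get("groups") or {}).items():
            if n < 1:
                problems.append(f"behavior group {g!r}: size must be >= 1")
        if behavior.get("n_frames", 0) < 1000:
            problems.append("behavior.n_frames must be >= 1000")
        for day in behavior.get("days", []):
            if day not in ("day1", "day2"):
                problems.append(f"behavior day {day!r} not supported")
    return problems


def simulate_study(config: dict | None, seed: int) -> StudyBundle:
    """Generate every contrast cohort and behavioral ethogram of a study.

    ``config`` follows :func:`default_study_config`; all violations are
    collected and reported together.  Independent seed substreams are
    spawned per contrast and per (group, day, animal) ethogram and logged
    in the returned bundle.
    """
    config = config if config is not None else default_study_config()
    problems = _validate_study_config(config)
    if problems:
        raise ConfigError("invalid study config: " + "; ".join(problems))

    root = np.random.SeedSequence(seed)
    counts_ss, behavior_ss = root.spawn(2)
    ccfg = config["counts"]
    contrasts: dict[str, SimulatedContrast] = {}
    seed_log: dict = {"contrasts": {}, "ethograms": {}}
    contrast_streams = counts_ss.spawn(len(ccfg["contrasts"]))
    for (name, cspec), ss in zip(ccfg["contrasts"].items(), contrast_streams):
        t, c = cspec["treatment"], cspec["control"]
        groups = [
            GroupSpec(t["label"], t["n"], t.get("batch", "b1"), treatment=1),
            GroupSpec(c["label"], c["n"], c.get("batch", "b1")),
        ]
        bridge_label = None
        if "bridge" in cspec:
            b = cspec["bridge"]
            for batch in b["batches"]:
                groups.append(
                    GroupSpec(f"{b['label']}@{batch}", b["n"], batch, bridge=1)
                )
            bridge_label = b["label"]
        batches = list(dict.fromkeys(g.batch for g in groups))
        design = StudyDesign(
            groups, batches, ccfg["n_regions"],
            tuple(ccfg.get("total_count_law", (11.0, 0.4))),
        )
        effects = EffectSpec.null(ccfg["n_regions"], ccfg.get("dispersion", 2.0))
        planted = cspec.get("planted")
        if planted:
            effects = effects.with_planted(
                planted["n_regions"], planted.get("log_fc", 1.0)
            )
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        table, meta = simulate_counts(design, effects, sub_seed)
        if bridge_label is not None:
            # collapse per-batch bridge groups to one label for the contrast
            merged = meta.frame.copy()
            merged.loc[
                merged["group"].str.startswith(f"{bridge_label}@"), "group"
            ] = bridge_label
            meta = AnimalMeta(merged)
        contrast = ContrastSpec(
            treatment=t["label"], control=c["label"], bridge=bridge_label
        )
        contrasts[name] = SimulatedContrast(table, meta, contrast, effects)
        seed_log["contrasts"][name] = sub_seed

    ethograms: dict[str, dict[str, list[eth.Ethogram]]] = {}
    bcfg = config.get("behavior")
    if bcfg:
        group_streams = behavior_ss.spawn(len(bcfg["groups"]))
        for (glabel, n), gss in zip(bcfg["groups"].items(), group_streams):
            bias = bcfg.get("day2_bias", {}).get(glabel, 0.2)
            spec = default_behavior_spec(day2_bias=bias)
            ethograms[glabel] = {}
            seed_log["ethograms"][glabel] = {}
            day_streams = gss.spawn(len(bcfg["days"]))
            for day, dss in zip(bcfg["days"], day_streams):
                seeds = [
                    int(s.generate_state(1)[0] % (2**31)) for s in dss.spawn(n)
                ]
                ethograms[glabel][day] = [
                    simulate_ethogram(
                        spec, bcfg["n_frames"], day, sd,
                        animal=f"{glabel}-{i + 1:02d}", group=glabel,
                    )
                    for i, sd in enumerate(seeds)
                ]
                seed_log["ethograms"][glabel][day] = seeds
    return StudyBundle(contrasts, ethograms, seed, seed_log)
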
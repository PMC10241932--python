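"""Post-clustering behavioral statistics for open-field ethograms.

An ethogram assigns one of six behavioral states (slow explore, grooming,
fast explore, reared, turning walk, locomotion) to every video frame,
together with the animal's centroid position and velocity.  Locomotion can
be further split into slow / medium / fast by centroid velocity, giving an
eight-state alphabet.  This module implements the downstream statistics:
majority filtering of predicted labels, state occupancies and day-over-day
habituation ratios of group geometric means, change-only transition
matrices and occupancy-weighted group shifts, sliding-window state
probabilities, open-field centroid metrics, and compositional analysis
(isometric log-ratio transform, bootstrap confidence intervals, and a
permutation Wilks-lambda group test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import ValidationError

logger = logging.getLogger(__name__)

#: Six-state alphabet, in the conventional listing order.
STATES6 = (
    "slow_explore", "grooming", "fast_explore", "reared", "turning_walk",
    "locomotion",
)

#: Eight-state alphabet after the locomotion split.
STATES8 = (
    "slow_explore", "grooming", "fast_explore", "reared", "turning_walk",
    "locomotion_slow", "locomotion_medium", "locomotion_fast",
)

#: States ordered from least to most active (by typical centroid speed);
#: used to interpret transition shifts "toward less-active states".
ACTIVITY_ORDER = (
    "grooming", "reared", "slow_explore", "fast_explore", "turning_walk",
    "locomotion",
)

DEFAULT_FRAME_RATE = 80.0
#: Default analysis span: first 18 min 46 s at 80 Hz.
DEFAULT_ANALYSIS_FRAMES = 90_080


@dataclass
class Ethogram:
    """Per-frame state labels plus centroid kinematics for one recording."""

    states: np.ndarray
    x: np.ndarray
    y: np.ndarray
    velocity: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    day: str = "day1"
    animal: str = ""
    group: str = ""
    alphabet: tuple[str, ...] = STATES6

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.velocity = np.asarray(self.velocity, float)
        n = len(self.states)
        if not (len(self.x) == len(self.y) == len(self.velocity) == n):
            raise ValidationError("states, positions and velocities differ in length")
        unknown = set(self.states) - set(self.alphabet)
        if unknown:
            raise ValidationError(f"states outside the alphabet: {sorted(unknown)}")
        if np.any(self.velocity < 0):
            raise ValidationError("velocities must be nonnegative")

    def __len__(self) -> int:
        return len(self.states)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "state": self.states,
                "x": self.x,
                "y": self.y,
                "velocity": self.velocity,
            }
        )


def write_ethogram(eth: Ethogram, path) -> None:
    eth.to_frame().to_csv(path, index=False)


def read_ethogram(
    path,
    frame_rate: float = DEFAULT_FRAME_RATE,
    day: str = "day1",
    animal: str = "",
    group: str = "",
    alphabet: tuple[str, ...] = STATES6,
) -> Ethogram:
    frame = pd.read_csv(path)
    needed = {"state", "x", "y", "velocity"}
    if not needed <= set(frame.columns):
        raise ValidationError(f"ethogram CSV needs columns {sorted(needed)}")
    return Ethogram(
        frame["state"].to_numpy(object), frame["x"].to_numpy(float),
        frame["y"].to_numpy(float), frame["velocity"].to_numpy(float),
        frame_rate, day, animal, group, alphabet,
    )


# ---------------------------------------------------------------------------
# state-sequence operations
# ---------------------------------------------------------------------------


def majority_filter(states, window: int = 11) -> np.ndarray:
    """Replace each label by the modal label in its centered window.

    Edge frames use the truncated window.  Ties keep the current label when
    it is among the modes, otherwise the alphabetically first mode; output
    length equals input length.
    """
    states = np.asarray(states, dtype=object)
    if states.size == 0:
        raise ValidationError("empty state sequence")
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return states.copy()
    labels, inv = np.unique(states, return_inverse=True)
    n, s = len(states), len(labels)
    onehot = np.zeros((n, s))
    onehot[np.arange(n), inv] = 1.0
    cum = np.vstack([np.zeros((1, s)), np.cumsum(onehot, axis=0)])
    half = window // 2
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    counts = cum[hi] - cum[lo]
    maxc = counts.max(axis=1)
    current_is_mode = counts[idx, inv] >= maxc - 1e-9
    modal = labels[np.argmax(counts, axis=1)]
    return np.where(current_is_mode, states, modal)


def split_locomotion(
    states, velocity, thresholds: tuple[float, float] = (2.0, 5.0)
) -> np.ndarray:
    """Relabel locomotion frames as slow/medium/fast by centroid velocity.

    Bins are half-open: [0, v_slow) -> slow, [v_slow, v_fast) -> medium,
    [v_fast, inf) -> fast; non-locomotion frames are untouched.
    """
    v_slow, v_fast = thresholds
    if not v_slow < v_fast:
        raise ValidationError("need v_slow < v_fast")
    states = np.asarray(states, dtype=object)
    velocity = np.asarray(velocity, float)
    if len(states) != len(velocity):
        raise ValidationError("states and velocity differ in length")
    if np.any(velocity < 0):
        raise ValidationError("velocities must be nonnegative")
    out = states.copy()
    loco = states == "locomotion"
    out[loco & (velocity < v_slow)] = "locomotion_slow"
    out[loco & (velocity >= v_slow) & (velocity < v_fast)] = "locomotion_medium"
    out[loco & (velocity >= v_fast)] = "locomotion_fast"
    return out


def occupancy(
    states, segments: dict[str, tuple[int, int]], alphabet=None
) -> pd.DataFrame:
    """Fraction of frames spent in each state, per segment (rows sum to 1)."""
    states = np.asarray(states, dtype=object)
    alphabet = tuple(alphabet) if alphabet is not None else tuple(
        sorted(set(states))
    )
    rows = {}
    for name, (start, stop) in segments.items():
        if not (0 <= start < stop <= len(states)):
            raise ValidationError(
                f"segment {name!r} = [{start}, {stop}) outside sequence "
                f"of length {len(states)} or empty"
            )
        seg = states[start:stop]
        rows[name] = [float(np.mean(seg == a)) for a in alphabet]
    return pd.DataFrame(rows, index=list(alphabet)).T


def default_segments(n_frames: int, frame_rate: float = DEFAULT_FRAME_RATE):
    """First 5 minutes vs the remainder of the recording."""
    cut = int(round(300 * frame_rate))
    if not 0 < cut < n_frames:
        raise ValidationError("recording too short for a 5-minute split")
    return {"first_5min": (0, cut), "remainder": (cut, n_frames)}


# ---------------------------------------------------------------------------
# habituation ratios and compositional tools
# ---------------------------------------------------------------------------


def replace_zeros(occ: pd.DataFrame, pseudo: float) -> pd.DataFrame:
    """Multiplicative zero replacement: zeros -> pseudo, nonzeros rescaled."""
    if pseudo <= 0:
        raise ValidationError("pseudo-fraction must be positive")
    arr = occ.to_numpy(float).copy()
    zeros = arr <= 0
    nz = zeros.sum(axis=1, keepdims=True)
    arr = np.where(zeros, pseudo, arr * (1.0 - nz * pseudo))
    return pd.DataFrame(arr, index=occ.index, columns=occ.columns)


def _prepare_occ(occ: pd.DataFrame, zero_policy: str, pseudo: float | None):
    if (occ.to_numpy() <= 0).any():
        if zero_policy == "strict":
            i, j = np.argwhere(occ.to_numpy() <= 0)[0]
            raise ValidationError(
                f"zero occupancy for animal={occ.index[i]!r}, "
                f"state={occ.columns[j]!r} under strict policy"
            )
        pseudo = pseudo if pseudo is not None else 1.0 / (2.0 * DEFAULT_ANALYSIS_FRAMES)
        return replace_zeros(occ, pseudo)
    return occ


def geometric_mean(occ: pd.DataFrame) -> pd.Series:
    """Per-state geometric mean over animals (rows)."""
    return np.exp(np.log(occ.astype(float)).mean(axis=0))


def habituation_ratio(
    occ_day1: pd.DataFrame,
    occ_day2: pd.DataFrame,
    zero_policy: str = "replace",
    pseudo: float | None = None,
) -> pd.Series:
    """Per-state ratio of group geometric means, day 2 / day 1.

    A ratio near 1 means no day-over-day change (failed habituation for
    states whose occupancy normally declines).  Zeros are handled by
    multiplicative replacement with a pseudo-fraction of one half frame per
    recording by default (``zero_policy="strict"`` rejects instead).
    """
    if list(occ_day1.columns) != list(occ_day2.columns):
        raise ValidationError("day-1 and day-2 occupancies must share states")
    g1 = geometric_mean(_prepare_occ(occ_day1, zero_policy, pseudo))
    g2 = geometric_mean(_prepare_occ(occ_day2, zero_policy, pseudo))
    return g2 / g1


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """Change-only transition probabilities: zero diagonal, stochastic rows.

    Rows for states with no observed outgoing transition are NaN and listed
    in ``silent_states`` (never silently zero-filled); ``empty`` marks a
    constant input sequence.
    """

    probs: pd.DataFrame
    counts: pd.DataFrame
    empty: bool = False
    silent_states: list[str] = field(default_factory=list)


def transition_matrix(states, alphabet=None) -> TransitionMatrix:
    states = np.asarray(states, dtype=object)
    if states.size == 0:
        raise ValidationError("empty state sequence")
    alphabet = list(alphabet) if alphabet is not None else sorted(set(states))
    index = {a: i for i, a in enumerate(alphabet)}
    runs = states[np.r_[True, states[1:] != states[:-1]]]
    counts = np.zeros((len(alphabet), len(alphabet)))
    for a, b in zip(runs[:-1], runs[1:]):
        counts[index[a], index[b]] += 1
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        probs = counts / row_sums[:, None]
    silent = [a for a, s in zip(alphabet, row_sums) if s == 0]
    empty = len(runs) < 2
    if empty:
        logger.warning("transition_matrix: constant sequence, empty matrix")
    return TransitionMatrix(
        pd.DataFrame(probs, index=alphabet, columns=alphabet),
        pd.DataFrame(counts.astype(int), index=alphabet, columns=alphabet),
        empty, silent,
    )


def group_average_transitions(
    matrices: list[TransitionMatrix], occupancies: list[pd.Series]
) -> pd.DataFrame:
    """Occupancy-weighted group average of per-animal transition matrices.

    Row *i* of the group matrix averages the animals' row-*i* transition
    probabilities weighted by each animal's probability of being in state
    *i*; animals with no outgoing transition from *i* contribute nothing to
    that row.  Rows with zero total weight are NaN (flagged missing).
    """
    if len(matrices) != len(occupancies) or not matrices:
        raise ValidationError("need matching, nonempty matrices and occupancies")
    alphabet = list(matrices[0].probs.index)
    num = np.zeros((len(alphabet), len(alphabet)))
    den = np.zeros(len(alphabet))
    for tm, occ in zip(matrices, occupancies):
        if list(tm.probs.index) != alphabet:
            raise ValidationError("transition matrices use different alphabets")
        p = tm.probs.to_numpy(float)
        w = occ.reindex(alphabet).fillna(0.0).to_numpy(float)
        defined = ~np.isnan(p).any(axis=1)
        num[defined] += w[defined, None] * p[defined]
        den[defined] += w[defined]
    with np.errstate(invalid="ignore"):
        avg = num / den[:, None]
    missing = [a for a, d in zip(alphabet, den) if d == 0]
    if missing:
        logger.warning("group_average_transitions: no data for rows %s", missing)
    return pd.DataFrame(avg, index=alphabet, columns=alphabet)


def group_transition_shift(
    day1_matrices, day1_occupancies, day2_matrices, day2_occupancies
) -> pd.DataFrame:
    """Day-2 minus day-1 occupancy-weighted group transition matrices."""
    avg1 = group_average_transitions(day1_matrices, day1_occupancies)
    avg2 = group_average_transitions(day2_matrices, day2_occupancies)
    return avg2 - avg1


# ---------------------------------------------------------------------------
# time-resolved state probability and open-field metrics
# ---------------------------------------------------------------------------


def sliding_state_probability(states, target: str, window: int = 20001) -> np.ndarray:
    """Centered moving fraction of frames in ``target`` (valid windows only).

    Output has length ``n - window + 1``; element *t* is the fraction of
    frames in the target state within the full window starting at frame *t*.
    """
    states = np.asarray(states, dtype=object)
    if window < 1 or window > len(states):
        raise ValidationError(
            f"window {window} outside [1, {len(states)}]"
        )
    indicator = (states == target).astype(float)
    return np.convolve(indicator, np.full(window, 1.0 / window), mode="valid")


@dataclass
class OpenFieldMetrics:
    distance: float
    inner_fraction: float
    n_missing: int


def open_field_metrics(
    x, y, margin: float = 150.0, bounds: tuple[float, float, float, float] | None = None
) -> OpenFieldMetrics:
    """Distance traveled and fraction of time in the inner arena.

    Distance sums Euclidean frame-to-frame displacements.  The inner region
    is the set of positions strictly farther than ``margin`` pixels from
    every border; borders default to the extent of the space the animal
    explored, or can be given explicitly as (xmin, xmax, ymin, ymax).
    Frames with missing positions are skipped and counted.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValidationError("need >= 2 frames of matching positions")
    valid = np.isfinite(x) & np.isfinite(y)
    n_missing = int((~valid).sum())
    if n_missing:
        logger.warning("open_field_metrics: skipped %d frames with missing "
                       "positions", n_missing)
    xv, yv = x[valid], y[valid]
    if len(xv) < 2:
        raise ValidationError("fewer than 2 frames with valid positions")
    distance = float(np.sum(np.hypot(np.diff(xv), np.diff(yv))))
    if bounds is None:
        xmin, xmax, ymin, ymax = xv.min(), xv.max(), yv.min(), yv.max()
    else:
        xmin, xmax, ymin, ymax = bounds
    border_dist = np.minimum.reduce([xv - xmin, xmax - xv, yv - ymin, ymax - yv])
    return OpenFieldMetrics(distance, float(np.mean(border_dist > margin)), n_missing)


# ---------------------------------------------------------------------------
# compositional analysis
# ---------------------------------------------------------------------------


def ilr_basis(d: int) -> np.ndarray:
    """Orthonormal sequential-binary-partition (Helmert-type) ILR basis.

    Column *i* contrasts part *i* against the geometric mean of parts
    i+1..D; the resulting D x (D-1) matrix has orthonormal columns that are
    orthogonal to the all-ones vector, so the transform is an isometry from
    the simplex (Aitchison metric) to R^(D-1).
    """
    if d < 2:
        raise ValidationError("need at least 2 parts")
    v = np.zeros((d, d - 1))
    for i in range(d - 1):
        r = d - i - 1
        scale = np.sqrt(r / (r + 1.0))
        v[i, i] = scale
        v[i + 1:, i] = -scale / r
    return v


def _check_composition(arr: np.ndarray) -> None:
    if np.any(arr <= 0):
        raise ValidationError("composition parts must be strictly positive "
                              "(apply a zero policy first)")
    if np.any(np.abs(arr.sum(axis=-1) - 1.0) > 1e-6):
        raise ValidationError("composition parts must sum to 1")


def ilr_transform(composition) -> np.ndarray:
    """Isometric log-ratio coordinates of one or many D-part compositions."""
    arr = np.atleast_2d(np.asarray(composition, float))
    _check_composition(arr)
    logx = np.log(arr)
    clr = logx - logx.mean(axis=1, keepdims=True)
    coords = clr @ ilr_basis(arr.shape[1])
    return coords[0] if np.asarray(composition).ndim == 1 else coords


def ilr_inverse(coords, d: int | None = None) -> np.ndarray:
    """Map ILR coordinates back to the simplex (closure of exp(V z))."""
    arr = np.atleast_2d(np.asarray(coords, float))
    d = d if d is not None else arr.shape[1] + 1
    raw = np.exp(arr @ ilr_basis(d).T)
    comp = raw / raw.sum(axis=1, keepdims=True)
    return comp[0] if np.asarray(coords).ndim == 1 else comp


@dataclass
class CompositionCI:
    """Per-state log-ratio difference vs a reference group with bootstrap CI."""

    table: pd.DataFrame          # columns: point, lower, upper
    n_boot: int
    level: float = 0.95

    def __post_init__(self) -> None:
        bad = (self.table["lower"] > self.table["point"] + 1e-12) | (
            self.table["point"] > self.table["upper"] + 1e-12
        )
        if bad.any():
            raise ValidationError("CI bounds do not bracket the point estimate")


def bootstrap_logratio_ci(
    group_occ: pd.DataFrame,
    reference_occ: pd.DataFrame,
    n_boot: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    zero_policy: str = "replace",
    pseudo: float | None = None,
) -> CompositionCI:
    """Percentile bootstrap CI of the log ratio of group geometric means.

    Per state, the point estimate is log(GM_group / GM_reference); animals
    are resampled with replacement within each group, independently,
    ``n_boot`` times (default 5000).  Seeded and reproducible.
    """
    for name, occ in (("group", group_occ), ("reference", reference_occ)):
        if len(occ) < 2:
            raise ValidationError(f"{name} group needs >= 2 animals")
    if list(group_occ.columns) != list(reference_occ.columns):
        raise ValidationError("groups must share the same state columns")
    g = np.log(_prepare_occ(group_occ, zero_policy, pseudo).to_numpy(float))
    r = np.log(_prepare_occ(reference_occ, zero_policy, pseudo).to_numpy(float))
    point = g.mean(axis=0) - r.mean(axis=0)

    rng = np.random.default_rng(seed)
    gi = rng.integers(0, len(g), size=(n_boot, len(g)))
    ri = rng.integers(0, len(r), size=(n_boot, len(r)))
    boot = g[gi].mean(axis=1) - r[ri].mean(axis=1)
    lo, hi = np.quantile(boot, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
    table = pd.DataFrame(
        {"point": point, "lower": lo, "upper": hi}, index=group_occ.columns
    )
    return CompositionCI(table, n_boot, level)


def multivariate_group_test(
    coords, labels, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for a multivariate location difference on ILR coords.

    The statistic is Wilks' lambda, det(W)/det(T) with W the pooled
    within-group and T the total scatter; group labels are permuted.  When
    the scatter matrices are singular the test falls back to a trace
    statistic tr(B pinv(T)) (logged).  This permutation test stands in for
    a packaged nonparametric Wilks-lambda test and is documented as such.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    labels = np.asarray(labels)
    if len(labels) != len(coords):
        raise ValidationError("labels and coordinates differ in length")
    uniq = np.unique(labels)
    if len(uniq) < 2 or any((labels == u).sum() < 2 for u in uniq):
        raise ValidationError("need >= 2 groups with >= 2 animals each")

    centered = coords - coords.mean(axis=0)
    t_scatter = centered.T @ centered
    if np.allclose(t_scatter, 0):
        return 1.0  # all observations identical: no evidence of separation

    def wilks(lab):
        w = np.zeros_like(t_scatter)
        for u in uniq:
            sub = coords[lab == u]
            dev = sub - sub.mean(axis=0)
            w += dev.T @ dev
        sign_t, logdet_t = np.linalg.slogdet(t_scatter)
        sign_w, logdet_w = np.linalg.slogdet(w)
        if sign_t <= 0 or sign_w <= 0:
            return None
        return np.exp(logdet_w - logdet_t)

    def trace_stat(lab):
        w = np.zeros_like(t_scatter)
        for u in uniq:
            sub = coords[lab == u]
            dev = sub - sub.mean(axis=0)
            w += dev.T @ dev
        b = t_scatter - w
        return float(np.trace(b @ np.linalg.pinv(t_scatter)))

    obs = wilks(labels)
    use_trace = obs is None
    if use_trace:
        logger.warning("multivariate_group_test: singular scatter, "
                       "falling back to trace statistic")
        obs = trace_stat(labels)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        if use_trace:
            stat = trace_stat(perm)
            hits += stat >= obs - 1e-12
        else:
            stat = wilks(perm)
            stat = 0.0 if stat is None else stat
            hits += stat <= obs + 1e-12
    return (1.0 + hits) / (1.0 + n_perm)
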
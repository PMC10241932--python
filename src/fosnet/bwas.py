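"""Region-wise negative-binomial contrasts: the brain-wide association study.

For one treatment-vs-control contrast and each brain region *j*, counts are
modelled as

    Y_ij ~ NegativeBinomial(mu_ij, phi_j)
    log(mu_ij) = beta0_j + X_i beta1_j + ln(T_i) + Z_i beta2_j + A_i beta3_j

with variance mu + mu^2/phi.  ``X_i`` indicates treatment, ``ln(T_i)`` is a
fixed offset (total counts of brain *i*) so that ``beta1`` measures the log
change in the *proportion* of total activation, ``Z_i`` are batch
indicators, and ``A_i`` marks a *bridge* group: an experimental condition
present in both the treatment batch and the control batch, which makes the
treatment effect identifiable even when treatment and control animals were
never processed together.

Effect sizes are Wald z statistics (coefficient / standard error) referred
to a standard normal null, with Benjamini-Hochberg control of the false
discovery rate across regions within each contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .counts import AnimalMeta, CountTable, ValidationError

logger = logging.getLogger(__name__)

PHI_FLOOR = 1e-4
PHI_CEIL = 1e7


class FitError(RuntimeError):
    """Raised when a single-region NB fit cannot be computed."""


class DesignError(ValueError):
    """Raised when a contrast's design matrix is invalid or unidentifiable."""


# ---------------------------------------------------------------------------
# contrast specification and design matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSpec:
    """Treatment-vs-control contrast with optional batch and bridge covariates."""

    treatment: str
    control: str
    batch_covariates: tuple[str, ...] = ()
    bridge: str | None = None
    alpha: float = 0.05
    fdr_method: str = "bh"

    def __post_init__(self) -> None:
        if self.treatment == self.control:
            raise DesignError("treatment and control groups must differ")
        if self.bridge in (self.treatment, self.control):
            raise DesignError("bridge group must differ from treatment and control")


@dataclass
class Design:
    matrix: np.ndarray          # n x p
    columns: list[str]
    offset: np.ndarray          # ln(T_i)
    animals: list[str]


def build_design(
    meta: AnimalMeta, totals: pd.Series, contrast: ContrastSpec
) -> Design:
    """Assemble (intercept, X, Z..., A) design with ln-total offset.

    Animals from the treatment, control and (if set) bridge groups enter in
    metadata order.  Batch indicator columns are included for every batch
    beyond the reference (the first batch in sorted order, or the batches
    named in ``contrast.batch_covariates``); they are omitted entirely when
    all included animals share one batch.  A rank-deficient design -- e.g.
    treatment and control in disjoint batches with no bridge group -- is
    rejected with an explanation rather than silently fitted.
    """
    wanted = {contrast.treatment, contrast.control}
    if contrast.bridge is not None:
        wanted.add(contrast.bridge)
    animals = [a for a in meta.animals if meta.frame.loc[a, "group"] in wanted]
    for g in wanted:
        if not any(meta.frame.loc[a, "group"] == g for a in animals):
            raise DesignError(f"group {g!r} has no animals with metadata")
    missing = [a for a in animals if a not in totals.index or totals[a] <= 0]
    if missing:
        raise DesignError(f"animals without positive totals: {missing}")

    groups = meta.frame.loc[animals, "group"]
    batches = meta.frame.loc[animals, "batch"]
    x = (groups == contrast.treatment).to_numpy(float)

    if contrast.batch_covariates:
        batch_levels = list(contrast.batch_covariates)
    else:
        present = sorted(batches.unique())
        batch_levels = present[1:]  # first sorted batch is the reference

    cols = [np.ones(len(animals)), x]
    names = ["intercept", "X"]
    for b in batch_levels:
        cols.append((batches == b).to_numpy(float))
        names.append(f"Z[{b}]")
    if contrast.bridge is not None:
        cols.append((groups == contrast.bridge).to_numpy(float))
        names.append("A")

    matrix = np.column_stack(cols)
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        hint = (
            "treatment is confounded with batch; supply a bridge group "
            "present in both batches"
            if contrast.bridge is None
            else "design columns are linearly dependent"
        )
        raise DesignError(f"rank-deficient design for contrast "
                          f"{contrast.treatment!r} vs {contrast.control!r}: {hint}")
    offset = np.log(totals.loc[animals].to_numpy(float))
    return Design(matrix, names, offset, animals)


# ---------------------------------------------------------------------------
# negative-binomial GLM with log link and offset
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    return float(
        np.sum(
            gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
            + phi * (np.log(phi) - np.log(phi + mu))
            + y * (np.log(mu) - np.log(phi + mu))
        )
    )


def _irls_beta(y, X, offset, phi, beta, tol=1e-10, max_iter=50):
    """Weighted least-squares updates for beta with phi held fixed."""
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu * phi / (mu + phi)          # 1 / Var(y) * (dmu/deta)^2
        z = (eta - offset) + (y - mu) / mu
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular weighted least-squares system: {exc}") from exc
        if not np.all(np.isfinite(beta_new)):
            raise FitError("divergent coefficient update (separation?)")
        step = np.max(np.abs(beta_new - beta) / (1.0 + np.abs(beta)))
        beta = beta_new
        if step < tol:
            break
    return beta


def _ml_phi(y, mu):
    """One-dimensional ML update of the dispersion on the log scale."""
    res = minimize_scalar(
        lambda lp: -_nb_loglik(y, mu, np.exp(lp)),
        bounds=(np.log(PHI_FLOOR), np.log(PHI_CEIL)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


@dataclass
class NBFit:
    coef: np.ndarray
    se: np.ndarray
    phi: float
    converged: bool
    n_iter: int
    loglik: float
    phi_at_boundary: bool
    columns: list[str] = field(default_factory=list)


def fit_nb_glm(
    y,
    design: np.ndarray | Design,
    offset=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NBFit:
    """Maximum-likelihood NB regression via alternating beta / phi updates.

    Coefficients are updated by iteratively reweighted least squares with the
    dispersion fixed, then the dispersion by one-dimensional likelihood
    maximization with the coefficients fixed, alternating until the joint
    relative change drops below ``tol`` (default 1e-8) or ``max_iter``
    iterations.  Non-convergence is reported in the result, never silently
    accepted.  ``phi`` is kept in [1e-4, 1e7]; fits at either boundary are
    flagged (the upper boundary is the Poisson limit).
    """
    if isinstance(design, Design):
        X, offset, columns = design.matrix, design.offset, design.columns
    else:
        X, columns = np.asarray(design, float), []
    y = np.asarray(y, float)
    offset = np.zeros(len(y)) if offset is None else np.asarray(offset, float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(offset) != X.shape[0]:
        raise FitError(
            f"length mismatch: y={len(y)}, design rows={X.shape[0]}, "
            f"offset={len(offset)}"
        )
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more observations ({n}) than parameters ({p})")
    if np.all(y == 0):
        raise FitError("all-zero response")

    beta = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    excess = np.sum((y - mu) ** 2 - mu)
    phi = float(np.clip(np.sum(mu**2) / excess if excess > 0 else PHI_CEIL,
                        PHI_FLOOR, PHI_CEIL))

    converged = False
    it = 0
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        beta_new = _irls_beta(y, X, offset, phi, beta)
        mu = np.exp(np.clip(X @ beta_new + offset, -30, 30))
        phi_new = _ml_phi(y, mu)
        delta_beta = float(np.max(np.abs(beta_new - beta) / (1.0 + np.abs(beta))))
        delta_phi = abs(np.log(phi_new) - np.log(phi)) / (1.0 + abs(np.log(phi)))
        ll = _nb_loglik(y, mu, phi_new)
        beta, phi = beta_new, phi_new
        # phi is weakly identified when the data are near-Poisson: accept
        # convergence once the coefficients and the likelihood have settled,
        # even if the (flat) dispersion direction still jitters
        if max(delta_beta, delta_phi) < tol or (
            delta_beta < tol and abs(ll - prev_ll) <= tol * (1.0 + abs(ll))
        ):
            converged = True
            break
        prev_ll = ll

    w = mu * phi / (mu + phi)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    at_boundary = phi <= PHI_FLOOR * 1.001 or phi >= PHI_CEIL * 0.999
    return NBFit(beta, se, phi, converged, it, _nb_loglik(y, mu, phi),
                 at_boundary, columns)


# ---------------------------------------------------------------------------
# multiple testing, effect sizes, full contrast
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving, <= 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(beta1: float) -> float:
    """exp(beta1): multiplicative change in activation proportion."""
    if not np.isfinite(beta1):
        raise ValidationError("fold change requires a finite coefficient")
    return float(np.exp(beta1))


@dataclass
class RegionFit:
    region: str
    status: str                      # ok | dropped-qc | fit-failed
    reason: str = ""
    beta1: float = np.nan
    se1: float = np.nan
    phi: float = np.nan
    z: float = np.nan
    p: float = np.nan
    q: float = np.nan
    fold: float = np.nan
    coef: np.ndarray | None = None
    n_iter: int = 0
    loglik: float = np.nan


@dataclass
class BWASResult:
    contrast: ContrastSpec
    fits: list[RegionFit]
    design_columns: list[str]
    n_animals: int

    @property
    def ok_fits(self) -> list[RegionFit]:
        return [f for f in self.fits if f.status == "ok"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [f.region for f in self.fits],
                "beta1": [f.beta1 for f in self.fits],
                "se": [f.se1 for f in self.fits],
                "phi": [f.phi for f in self.fits],
                "z": [f.z for f in self.fits],
                "p": [f.p for f in self.fits],
                "q": [f.q for f in self.fits],
                "fold": [f.fold for f in self.fits],
                "status": [f.status for f in self.fits],
                "reason": [f.reason for f in self.fits],
            }
        ).set_index("region")


def run_contrast(
    table: CountTable, meta: AnimalMeta, contrast: ContrastSpec
) -> BWASResult:
    """Fit the NB contrast for every region; Wald p-values, BH q across regions.

    Regions with no nonzero counts are dropped before fitting, and regions
    whose fit fails or does not converge are flagged; neither kind enters the
    FDR denominator (q-values are computed across successfully analyzed
    regions only, within this contrast).
    """
    design = build_design(meta, table.totals, contrast)
    x_idx = design.columns.index("X")
    fits: list[RegionFit] = []
    for region in table.regions:
        y = table.counts.loc[design.animals, region].to_numpy(float)
        if not np.any(y > 0):
            fits.append(RegionFit(region, "dropped-qc", "all-zero counts"))
            continue
        try:
            fit = fit_nb_glm(y, design)
        except FitError as exc:
            fits.append(RegionFit(region, "fit-failed", str(exc)))
            continue
        if not fit.converged:
            fits.append(
                RegionFit(region, "fit-failed",
                          f"no convergence in {fit.n_iter} iterations")
            )
            continue
        b1, s1 = float(fit.coef[x_idx]), float(fit.se[x_idx])
        if not np.isfinite(s1) or s1 <= 0:
            fits.append(RegionFit(region, "fit-failed", "non-positive SE"))
            continue
        z = b1 / s1
        fits.append(
            RegionFit(
                region, "ok", "", b1, s1, fit.phi, z,
                float(2.0 * norm.sf(abs(z))), np.nan, fold_change(b1),
                fit.coef, fit.n_iter, fit.loglik,
            )
        )
    ok = [f for f in fits if f.status == "ok"]
    if not ok:
        raise ValidationError("no analyzable regions in contrast")
    q = bh_adjust([f.p for f in ok])
    for f, qv in zip(ok, q):
        f.q = float(qv)
    n_dropped = len(fits) - len(ok)
    if n_dropped:
        logger.info("run_contrast: %d of %d regions dropped or failed",
                    n_dropped, len(fits))
    return BWASResult(contrast, fits, design.columns, len(design.animals))


def permutation_check(
    fractions: pd.DataFrame,
    meta: AnimalMeta,
    contrast: ContrastSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Label-permutation p-values for the two-sample mean difference in fractions.

    A validity check on the parametric Wald p-values: per region, the
    statistic is |mean(treatment) - mean(control)| of the normalized
    fractions, with p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    t_animals = [a for a in meta.animals_in_group(contrast.treatment)
                 if a in fractions.index]
    c_animals = [a for a in meta.animals_in_group(contrast.control)
                 if a in fractions.index]
    if len(t_animals) < 2 or len(c_animals) < 2:
        raise ValidationError("each group needs >= 2 animals")
    data = fractions.loc[t_animals + c_animals].to_numpy(float)
    n_t, n = len(t_animals), len(t_animals) + len(c_animals)
    base = np.full(n, -1.0 / (n - n_t))
    base[:n_t] = 1.0 / n_t
    obs = np.abs(base @ data)

    rng = np.random.default_rng(seed)
    perm_w = np.empty((n_perm, n))
    for b in range(n_perm):
        perm_w[b] = base[rng.permutation(n)]
    perm = np.abs(perm_w @ data)
    p = (1.0 + (perm >= obs[None, :] - 1e-15).sum(axis=0)) / (1.0 + n_perm)
    return pd.Series(p, index=fractions.columns, name="perm_p")
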
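# Methods

This note documents the statistical models implemented in `fosnet`, the
defaults of the synthetic-data generator, the numerical choices, and what
the tests do and do not establish about real data.

## Count model and estimation

Each brain region is analyzed independently. For animal *i* and region *j*,

    Y_ij ~ NegativeBinomial(mu_ij, phi_j),   Var = mu + mu^2 / phi,
    log(mu_ij) = beta0_j + X_i beta1_j + ln(T_i) + Z_i beta2_j + A_i beta3_j.

The offset `ln(T_i)` conditions on each animal's total count, so `beta1_j`
is the log change in the *proportion* of brain-wide activation attributable
to region *j* under treatment. Batch indicators `Z` absorb processing
batches; when treatment and control never co-occur in a batch, a *bridge*
group (one condition present in both batches, indicator `A`) restores
identifiability, and `build_design` refuses rank-deficient designs rather
than fitting them.

Estimation alternates (a) iteratively reweighted least squares for the
coefficients with the dispersion fixed (weights `mu*phi/(mu+phi)`, the
inverse variance times the squared link derivative) and (b) a bounded
one-dimensional likelihood maximization for `phi` on the log scale, until
the joint relative change falls below 1e-8 or 100 iterations. Because the
likelihood is nearly flat in `phi` for equidispersed data, convergence is
also accepted when the coefficients and the log-likelihood have both
settled even if the (weakly identified) dispersion still jitters; `phi` is
confined to [1e-4, 1e7] and boundary fits are flagged. Standard errors come
from the expected information at the estimates, with `phi` treated as
fixed, matching standard NB-GLM practice. Non-converging or degenerate
regions (all-zero counts, separation, singular systems) are reported with a
status and reason and excluded from the FDR denominator; they are never
silently accepted.

Wald z = beta1/SE is referred to the standard normal for a two-sided p,
deliberately without small-sample correction, and Benjamini–Hochberg
adjustment is applied within each contrast. **Known limitation:** at ten
animals per group the plug-in-dispersion Wald test is anti-conservative —
the measured size at alpha = 0.05 is ~0.08 for phi = 2, both for this
implementation and for an independent reference fitter on identical data.
The permutation check (`permutation_check`, label permutations of the
two-sample mean difference on normalized fractions) is provided precisely
to audit the parametric p-values; its own null p-values are uniform.

## Network inference

Within a group of M animals, Spearman rank correlations (average ranks for
ties) are computed between all pairs of regions that passed the BWAS screen
(default p < 0.05, a deliberately permissive within-group screen). Pairs
become edges when |rho| >= rho_threshold. The threshold starts at a floor
of 0.4 and is raised to the smallest observed |rho| value at which the
estimated FDR,

    FDR = P_threshold * pi0 * (k-1)(k-2) / (2C),

meets the target (default 0.05), where `P_threshold` is the two-tailed
Fisher-z p-value `2*normcdf(-atanh(rho_thr)*sqrt(M-3))`, `pi0` is the
Storey estimate `#{p > 0.5} / (0.5 m)` over all defined pairs, and `C`
counts supra-threshold pairs. The `(k-1)(k-2)/2` pair count is evaluated
verbatim as the procedure defines it; `pair_count="all"` switches to the
count of distinct pairs `k(k-1)/2` for sensitivity analysis. If no
candidate passes, an explicitly flagged empty-graph selection is returned.
Regions with zero rank variance have undefined correlations; these pairs
are excluded from C, from pair totals, and from edges, and are logged.

The edge rule uses |rho| (keeping the signed value on each edge), since the
graphs join both strongly positive and strongly negative pairs; lowering
the target FDR can only raise the selected threshold.

**Known limitation:** the procedure does not strictly control the realized
false-edge proportion in small groups. Under a global null (30 independent
regions), the mean realized false-edge proportion is ~0.20 at M=16, ~0.17
at M=22 and ~0.10 at M=58 against a 0.05 target. Two mechanisms, both
measured by Monte Carlo: the Fisher-z tail underestimates the exact
Spearman permutation tail by a factor of 2–4 at these M (e.g. P(|rho| >=
0.79) at M=16 is 4.5e-4 exactly vs 1.2e-4 by Fisher-z), and
`(k-1)(k-2)/2` undercounts the pairs actually scanned. Interpret sparse
selected graphs accordingly; the estimated FDR is reported with every
selection so this can be audited.

Layouts use classical (Torgerson) multidimensional scaling of the
dissimilarity `d = 1 - rho`: eigendecomposition of the double-centered
squared-dissimilarity matrix, top two axes, signs fixed by making each
axis's largest-magnitude coordinate positive. This is fully deterministic;
no stochastic stress majorization is involved. Undefined correlations are
imputed as rho = 0 (d = 1) with a warning.

The expression-tertile analysis ranks regions by mean fraction of total
counts (ties broken lexicographically), cuts at round(n/3) and round(2n/3)
(83 regions -> 28/27/28), counts within-tertile pairs with |rho| >= 0.4
over the pooled cohort, and compares tertiles with a two-sided Fisher exact
test (sum of hypergeometric point probabilities not exceeding the observed
table's, with the customary 1+1e-7 tie tolerance). The fixed 0.4 edge rule
is used for tertiles (rather than a group-specific selected threshold),
since the comparison pools all animals into a single cohort.

## Ethogram statistics

State sequences over the six-state alphabet are majority-filtered (window
11 frames, truncated at edges; ties keep the current label, otherwise the
alphabetically first mode). Locomotion is split into slow/medium/fast by
half-open centroid-velocity bins at configurable thresholds (defaults 2 and
5 px/frame; the cutoffs are a tuning choice, not an estimate). Occupancies
are computed per segment — by default the first 5 minutes vs the remainder
of an 80 Hz recording, with analysis spanning the first 90,080 frames
(18 min 46 s) when full recordings are supplied.

Habituation ratios divide day-2 by day-1 group geometric means of
occupancy, per state; a ratio near 1 flags failed habituation for states
whose occupancy normally declines. Because zero occupancies are certain in
short recordings, geometric-mean and log-ratio machinery defaults to
multiplicative zero replacement with a pseudo-fraction of half a frame per
recording, `1/(2 * 90080)`; a strict mode rejects zeros instead, naming the
offending animal and state. Group geometric means are taken over per-animal
occupancy fractions (not pooled frames).

Transition matrices count only changes of state (zero diagonal, rows
normalized over outgoing transitions); rows with no outgoing transitions
are NaN and flagged, never zero-filled. Group matrices weight each animal's
row *i* by that animal's probability of being in state *i*; the habituation
shift is the day-2 minus day-1 group matrix. Sliding-window state
probabilities use a centered 20,001-frame window over valid positions only
(output length n - window + 1); edge frames are not padded.

Open-field metrics: distance traveled sums frame-to-frame Euclidean
displacements; the inner-arena fraction is time spent strictly farther
than 150 px from every border, with borders estimated from the extent the
animal explored unless given explicitly. Frames with missing positions are
skipped and counted.

Compositional analysis maps occupancy compositions to isometric log-ratio
coordinates via the standard sequential-binary-partition (Helmert-type)
orthonormal basis, in which coordinate *i* contrasts part *i* against the
geometric mean of the remaining parts; the transform is an isometry and
`ilr_inverse` recovers compositions to machine precision. Group log-ratio
differences (vs a reference group, per state) get percentile bootstrap 95%
confidence intervals from 5,000 within-group animal resamples, seeded.
Measured coverage for a planted shift of ~0.5 with 12 animals per group is
~93–94% — the usual mild percentile-bootstrap undercoverage at this sample
size. The omnibus group test permutes labels of a Wilks-lambda statistic
(det within / det total scatter) on ILR coordinates, falling back to a
trace statistic when scatter matrices are singular; it is a permutation
stand-in for packaged nonparametric Wilks-lambda tests and is calibrated
under the null.

## Synthetic-data generator

The generator's defaults define the conditions under which the pipeline is
validated.

* **Totals.** `T_i` is log-normal with mean-log 11 and sd-log 0.4 (~6e4
  counts, coefficient of variation ~0.4), reflecting strong animal-to-
  animal variability in total counts; region counts are then drawn
  conditional on `T_i` through the offset, which is how the analysis model
  treats totals.
* **Baselines.** Region baseline rates span two orders of magnitude
  (geometric grid) and are normalized to proportions, so region means range
  from tens to thousands of counts. Dispersion defaults to phi = 2
  (strong overdispersion).
* **Cohorts.** The default study uses 16 treated vs 22 control animals —
  the perturbation-vs-control group sizes of the motivating design — with
  20 planted effects of |log FC| = 1, alternating sign, among 60 regions.
* **Correlation.** Inter-region dependence is induced by per-animal latent
  factors multiplying region rates through configurable loadings — the
  minimal mechanism that produces rank-correlated regional activity; it is
  not a mechanistic circuit model.
* **Ethograms.** Semi-Markov sequences over the six states with geometric
  dwell times by default (a pure Markov jump chain; a negative-binomial
  dwell option mimics smoothed real ethograms), state-specific gamma
  velocities ordered by activity level, and a reflected random-walk
  centroid in a 400x400 px arena at 80 Hz. Day-2 habituation is planted by
  redirecting a configurable fraction of each row's transition mass toward
  states less active than the source (default 0.2 for controls, 0.02 for
  the perturbed group, emulating absent habituation).
* **Streams.** Every generator spawns named seed substreams per group /
  day / animal, so adding a group never perturbs other groups' draws, and
  identical seeds give bitwise-identical data.

What the generator does *not* emulate: imaging artifacts, atlas
registration error, spatially correlated counting noise between adjacent
regions, heavy-tailed dwell distributions, pose-estimation noise, or arena
wall-following. Passing tests therefore demonstrate correctness of the
statistics under the stated models, not robustness to those real-data
features.

## Problem sizes used in validation

Validation runs use 2,000 regions for null calibration, 200 replicates for
network false-edge rates, 500 replicates x 5,000 resamples for bootstrap
coverage, 10^4 permutations for the Spearman null, six animals x 50,000
frames per day for transition-shift recovery, and full enumeration of all
2x2 tables with N <= 40 for the Fisher exact check. These sizes make every
Monte-Carlo standard error small relative to the tolerance being asserted.
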
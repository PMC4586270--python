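# Methods

This note documents the statistical models implemented in `emogonogo`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not establish.

## Task design generation

A session consists of `n_runs` runs of fixed duration (default four 330-s
runs at TR 2 s).  Session-level trial counts default to 84/80/20/20
(neutral Go / aversive Go / neutral NoGo / aversive NoGo): an 80/80/20/20
core preserving the 4:1 Go:NoGo ratio, plus one neutral-Go lead trial per
run, since the first trial of every run is always neutral Go.

Inter-trial intervals are drawn from {2, 4, 6} s with proportions
30/40/30%.  Integer counts are fixed by largest-remainder allocation, so
the session mean is exactly 4 s whenever the quotas are integral (61/82/61
at n = 204).  *ITI precedence:* each trial type's preceding-ITI counts are
allocated by largest remainder from the same 30/40/30 proportions, so every
type sees the session-wide ITI distribution to within one trial.  (Reading
"equal proportions" as uniform thirds per type is arithmetically
incompatible with a 30/40/30 overall mix; the proportional reading is the
one that satisfies both constraints simultaneously.)

*Transition balance:* first-order transition counts cannot be uniform when
the type marginals are 84/80/20/20, so sequences are built by a randomized
greedy construction (next type drawn among remaining types minimizing the
supply-normalized count of the candidate transition) and the best of
`n_attempts` (default 200) constructions by summed squared deviation from
the uniform transition target is kept; the achieved cost is recorded in the
design metadata and re-verified by the design checker.

*Run padding:* each run's slack between trial+ITI time and the run duration
becomes leading/trailing fixation, with at least 12 s of lead so that no
trial onset falls inside the six discarded lead-in volumes.  All onsets lie
on the 2-s volume grid.  Every generator is a pure function of its seed.

*Stimulus selection* ranks rating rows by Euclidean distance in
(arousal, valence) space within the valence strata (aversive: valence ≤ 3.6,
target [9, 1]; neutral: 3.6 < valence < 6.4, target [1, 5]); ties break by
id so selection is deterministic.

## Synthetic cohorts and BOLD data

Cohort scores are drawn from a bivariate Gaussian with configurable moments
(defaults: ARBS 15.6 ± 4.6, BIS 67.6 ± 16.1, correlation 0.78 — the
reference sample's statistics), rounded to integers and clipped to the
instruments' ranges.  Exactly `n_high` participants are forced to ARBS ≥ 17
and the rest to ≤ 13, excluding the 14–16 band to mirror the bimodal break
observed in the reference sample; draws are retried until the realized
correlation is within a tolerance (default 0.15) of the target.  BIS totals
are split into the six subscale sums within the per-subscale item-count
bounds, proportional to the sample's subscale profile.

The hemodynamic response is the conventional double-gamma (difference of
gamma densities; peak delay 6 s, undershoot delay 16 s, unit dispersions,
peak:undershoot 6:1) scaled to unit peak; it peaks near 5 s and is
effectively zero by 30 s.

A synthetic session is
`baseline + Σ_trials amplitude(region, type, participant) · h(t − onset)`
plus per-run linear drift and a slow sinusoid, an optional motion-like
component (smoothed random walk times a random spatial weight map), and
AR(p) noise whose innovations are spatially smoothed Gaussian fields
(variance renormalized after smoothing).  Amplitudes can be modulated
linearly in mean-centred ARBS and/or BIS scores per (region, trial type).
The first six volumes per run carry no task signal and are flagged for
discard, so the pipeline exercises the lead-in discard rule.  The
generator's ground truth (effects, noise, seed) is stored on the session
object and serialized beside any written data.

`expected_fir_betas` is a forward-model oracle — a dense least-squares
projection of the noiseless response onto the FIR basis plus the standard
nuisance columns — kept deliberately independent of the GLM fitting path.
Note one modelling fact it makes explicit: the double-gamma undershoot
extends beyond the 14-s FIR window, so even noise-free FIR estimates differ
from raw response samples by ~1–2%.  Exact-recovery statements therefore
refer either to this projection oracle or to the well-specified regime
(`hrf_duration=14`), both of which the tests use.

## First-level GLM

The design matrix holds 7 FIR indicator columns per trial type on the
post-discard volume grid (an eighth set for error trials when present,
removed from their type's set), and per-run nuisance: offset, linear drift,
cosine and sine with period twice the run length, and any caller-supplied
columns (motion parameters, noise-ROI means).  Autocorrelation is estimated
per slice: residuals of an initial OLS fit are pooled across the slice's
voxels within runs, the lag-1..10 sample autocorrelations converted to a
stationary AR(10) by Levinson–Durbin (reflection coefficients clipped to
|κ| < 1; trailing coefficients dropped if the polynomial is still
non-stationary).  The whitening transform is the exact inverse Cholesky
factor of the AR-process Toeplitz correlation matrix applied per run, so
the fit is exact GLS: with zero AR it reduces to OLS, and it matches a
dense GLS oracle to machine precision.  When residual power is negligible
relative to the data (noise-free input) the AR step is skipped — estimating
an AR model from deterministic misfit is meaningless and would perturb the
projection.  Degrees of freedom are volumes − rank(design).

Contrast effects are the contrast-weighted **mean** of each type's FIR
betas at timepoints 3 and 4 (4 and 6 s post-onset, the hemodynamic peak);
the sum is available via `combine="sum"`.  Standard errors come from the
whitened design's covariance and the per-voxel residual variance; t is
two-tailed.

## Group inference

Each of the three contrasts is fit voxelwise against three designs:
intercept only, and intercept + mean-centred ARBS or BIS.  The default fit
is a weighted mixed-effects regression: first-level variances plus a
DerSimonian–Laird (method-of-moments) random-effects variance floored at
zero; a plain OLS mode exists and is what the permutation calibrator uses.
Group df is n − rank by default with an override argument, since pooled-df
machinery from spatially regularized mixed-effects methods is out of scope.
Critical values are always computed from the t quantile function, never
hard-coded.

**Permutation calibration** shuffles trial-type labels within each
participant (onsets fixed), refits the first level (OLS, no AR re-fit, as
the calibration deliberately simulates a cheaper analysis), fits the OLS
second level, thresholds each of the nine maps two-tailed at the voxel p,
and records the maximum cluster size.  The returned extent is the smallest
k such that a max cluster ≥ k occurred in at most α of iterations.  By
default the null maxima are pooled across all nine maps (the published
procedure); per-map calibration is available (`pool_maps=False`).

**Monte Carlo calibration** (AlphaSim-style) smooths Gaussian white noise
to the target FWHM on a grid padded by two kernel widths (so the field is
stationary inside the mask), renormalizes variance within the mask,
thresholds two-tailed at the normal quantile, and collects max cluster
sizes.  **Residual smoothness** is estimated from variance-normalized
volumes via the lag-1 spatial correlation of first differences,
`FWHM = d·sqrt(2 ln 2 / (−ln ρ₁))` per axis (the Gaussian-kernel
convention used by the standard AFNI estimator), combined as a geometric
mean; it recovers a known 9-mm kernel within ~2% and is scale invariant.

Three facts about the two calibrations, established empirically by the test
suite on stationary synthetic nulls, are worth stating because they explain
large calibration gaps seen in practice:

1. Per map, permutation and Monte Carlo extents agree closely (within the
   granularity of small extents).
2. Pooling maxima across the nine (correlated) maps inflates the pooled
   permutation extent well above any single-field Monte Carlo value — a
   max-over-maps effect, not non-stationarity.
3. At small cohort sizes the second-level t-fields yield systematically
   larger clusters than a Gaussian field at the same voxelwise rate, and
   the mixed-effects analysis applied with an OLS-calibrated threshold is
   conservative (observed family-wise rate below α).

Consequently the family-wise error guarantee is exact for the analysis the
calibrator simulates, and conservative for the heavier mixed-effects
analysis — the same trade the published procedure makes.

Cluster connectivity defaults to faces-only (6-connectivity), configurable;
positive and negative suprathreshold voxels are clustered separately.
Cluster reports give peak mm coordinates (via the affine when available),
size, volume (size × voxel volume), and median t/p across member voxels.
**Timecourse QA** refits the cluster-mean timecourse with the FIR model and
correlates the across-type mean 7-point deconvolved timecourse with the
canonical double-gamma sampled at the FIR lags; the default cutoff is 0
(any positive correlation passes, replacing the published visual
inspection), with flat timecourses flagged indeterminate rather than
scored.  `grow_region` provides deterministic breadth-first peak-centred
region growth (frontier ordered by linear index) for QA region definition.

## Correlation-pattern analysis

Region-by-contrast values are the mean first-level contrast effect over
each atlas region's voxels (26 regions × 3 contrasts = 78 columns by
default).  Patterns are Pearson correlations of each column with an
instrument's scores; constant columns or scores are an error, never a
silent zero.  The similarity statistic is

    S = 1 − ‖c_a − c_b‖² / 78,

one minus the mean squared entrywise difference.  The statistic's published
verbal definition says "Euclidean distance", but its two published anchor
values (identical → 1; all-ones vs all-zeros → 0) and its reported
empirical mean (0.53) are only attainable with the squared form — the
literal Euclidean form divided by 78 is confined to [0.774, 1] for those
inputs — so the squared form is the default and `norm="euclidean"`
implements the literal reading.  S is symmetric, equals 1 iff the patterns
are identical, and lies in [−3, 1] for correlation-valued entries.

The split test stratifies participants by risk class (low/high, plus a mid
stratum if any), splits each stratum as evenly as possible with odd members
balanced so group sizes differ by at most one, computes instrument A's
pattern from group 1 and B's from group 2, and repeats (default 10,000
iterations).  Reported: mean, SD, proportion of S below 0.3 and above 0.7.
A property worth knowing when interpreting nulls: when the columns are
independent of both scores, S concentrates near 1 − 2·Var(r) ≈ 0.78 for
group size ~10 (the two patterns are then independent small-sample
correlation noise, not systematically different); S falls below the low
cutoff when the two instruments' true associations differ, not merely when
data are noisy.

## Behavioral statistics

BIS-11 scoring applies the instrument's published reversal set and
six-subscale partition, shipped as an editable YAML key rather than
hard-coded; subscale sums always equal the total.  The bootstrap-vs-zero
test is a one-sided percentile bootstrap of the mean (rates cannot be
negative; p reported at resolution 1/n_iter, degenerate all-zero data gives
p = 1).  The paired test is a sign-flip permutation of the differences,
two-sided on |mean|.  Bootstrap regression resamples residuals with
replacement onto fitted values and doubles the one-sided tail fraction of
resampled slopes.  Latency comparisons use the paired t-test.  Default
iteration count is 10,000 (the paper states none for these tests; the value
matches the pattern-analysis iteration count).

## Defaults that matter

| Parameter | Default | Meaning |
|---|---|---|
| TR | 2 s | volume time; trial duration = 1 volume |
| run duration / runs | 330 s × 4 | 165 volumes per run |
| discarded volumes | 6 per run | spin-saturation lead-in |
| FIR length | 7 | 0–12 s post-onset at 2-s spacing |
| contrast timepoints | {3, 4}, mean | 4–6 s, hemodynamic peak |
| AR order | 10 | per-slice pooled, Levinson-stabilized |
| voxel threshold | p < 0.01 two-tailed | t quantile at the map's df |
| cluster connectivity | faces | 6-connectivity |
| calibration α | 0.05 | family-wise, max-cluster based |
| pattern iterations / cutoffs | 10,000 / 0.3, 0.7 | split-resampling test |
| cohort | n = 21, 10 high-risk, r = 0.78 | reference-sample moments |

## What the synthetic tests establish — and what they do not

The generator reproduces the statistical structure the estimators assume:
linear superposition of double-gamma responses, AR temporal noise,
stationary Gaussian spatial smoothness, smooth drift.  Green tests
establish internal correctness (estimators recover what the generator
programmed, error rates are calibrated under the generator's null), not
fidelity to real 4.7-T BOLD data: no physiological noise spectra, motion
artifacts and spin-history effects, spatially non-stationary smoothness,
susceptibility dropout, or anatomically realistic masks and atlases.
Non-stationary smoothness in particular is known to make single-FWHM Monte
Carlo calibration anticonservative on real data, which is one reason the
permutation route is the default recommendation despite its cost.

Known numerical choices and limitations, collected: AR pooling is a
per-slice average (no spatial model within slice); whitening covariance is
the exact AR Toeplitz form, not a truncated approximation; group df is
analytic (n − rank) with an override rather than pooled; the Monte Carlo
mask for calibration-scale checks is a voxel-count-exact ellipsoid, not a
real brain mask; stimulus-selection operates on ratings only; ARBS item
content is not reproduced (totals are accepted directly, or an item table
with a caller-supplied key).
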
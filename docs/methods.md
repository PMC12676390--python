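# Methods

`neurolatent` implements a structure–function latent-variable analysis for
intracranial neurophysiology and cortical morphometry, together with synthetic
generators that plant known ground truth at every stage. This note documents
the models, the defaults and why they were chosen, and the numerical behaviour
a user should know about. No empirical claim here goes beyond what the test
suite and `scripts/acceptance.py` compute.

## Signal model and preprocessing

Recordings are multichannel resting time series (bipolar ECoG over premotor
PM, motor M1 and somatosensory S1 cortex, plus pallidal LFP channels labelled
`SubCort*`), sampled at `fs` Hz with a per-sample artifact mask.

**Line noise.** The default removal fits and subtracts the 60 Hz sine/cosine
pair by least squares (the DFT-filter approach common for intracranial data).
For a stationary mains tone this is exact and introduces no filter ringing; a
zero-phase IIR notch (`method="iir"`) is available for drifting line
amplitude, but its backward-pass edge transient alone contributes several
percent residual RMS on short records, which is why it is not the default.
Spectral normalization additionally excludes 60k ± 2 Hz for all harmonics in
range, so residual line energy never enters the features.

**Artifact repair.** Per channel: full-wave rectification → first difference →
5-point median filter → flag samples where the filtered derivative deviates
from its median by more than 5 × MAD (raw MAD, no 1.4826 consistency factor;
configurable) computed over the whole recording → replace flagged runs by
linear interpolation anchored 2 ms before/after, and mark them in the artifact
mask. Note the median-filter stage means the detector targets *sustained*
voltage slews (≥ 3 samples of elevated derivative); a one-sample step is
deliberately invisible to it. The synthetic spike generator therefore plants
triangular slews (`width_samples` up, `width_samples` down) rather than square
steps.

**Spectra.** Thomson multitaper PSD on 1 s consecutive non-overlapping
windows: time-half-bandwidth NW = 2 (±2 Hz smoothing at 1 s) with K = 3 DPSS
tapers, averaged over tapers then windows, restricted to 4–110 Hz. Spectra
are normalized to sum to 1 over included (non-line) bins; band power is the
mean normalized power over bins inside the closed band interval. Bands:
alpha 8–11, low beta 12–20, high beta 21–35, gamma 65–110 Hz. (An
introduction-style 13–20 Hz low beta exists in parts of the literature; the
12–20 Hz convention is the default here.)

**Bursts.** The band envelope is the analytic-signal magnitude of the
zero-phase (forward–backward) 4th-order Butterworth band-pass. Bursts are
maximal runs *strictly above* the subject's 75th-percentile envelope value
(computed over artifact-free samples only) lasting at least one cycle of the
band's center frequency (configurable to the lower edge). Runs are never
merged. Burst amplitude is the mean envelope within the burst (peak available
via configuration); burst rate divides the count by artifact-free duration.

### Duration bias of percentile-threshold bursts

A property worth stating explicitly: for a continuous envelope distribution,
the time spent strictly above the 75th percentile is *identically* 25% of the
(artifact-free) record. Hence, when all supra-threshold time falls into the
detected bursts,

    mean detected duration = 0.25 × T / (number of bursts),

independent of the true burst lengths. Detected durations are therefore
faithful only when the true burst time fraction is near 25%; at lower
fractions the threshold settles into the envelope's rising edges and durations
are biased upward by exactly the deficit. The planted-burst benchmark (10
bursts × 0.3 s) consequently uses a 12 s epoch (burst fraction 25%), where the
threshold self-balances mid-ramp and recovery is exact; the generator's
`min_duration_s` (default 15 s, the minimum usable resting epoch for the kind
of recordings emulated) is lowered explicitly for that fixture. On realistic
epochs (60 s, fraction ≪ 25%) the detector still finds every planted
high-amplitude event, but also counts baseline-level bursts — that is the
definition operating as designed, not an error (see
`analysis/02_signal_features.py`).

**Coherence.** Magnitude-squared coherence uses the same multitaper scheme:
cross- and auto-spectra averaged over windows and tapers, then
MSC = |S_xy|² / (S_xx S_yy), averaged over included band bins. At least two
windows are required (one window gives MSC ≡ 1). Windows containing repaired
samples are kept — repair is interpolation, not deletion.

**Feature vector.** Default enumeration: 4 metrics (power, burst duration,
amplitude, rate) × 4 bands × 4 sites = 64, plus cortico-cortical coherence for
{M1–PM, M1–S1} × 4 bands = 8, plus cortico-subcortical coherence for
{M1, PM, S1}×pallidum × 4 bands = 12, i.e. 84 canonical columns named
`<metric>.<band>.<site-or-pair>`. The published feature count for this kind of
study (92 over "five bands") is not recoverable from four named bands and two
named cortical pairs; the enumeration is config-driven, and adding a band adds
21 columns. The pallidal reference is the `SubCort` channel with the highest
mean normalized 12–35 Hz power. Absent channels yield missing values, not
errors; bilateral recordings are feature-averaged across hemispheres by
default (left/right selectable) — the aggregation rule for bilateral implants
is a genuine free choice and averaging is the variance-minimizing one.
Normalized power, burst duration/rate and coherence are invariant to channel
gain; burst amplitude scales linearly with gain, by design.

## Morphometry

FreeSurfer-style anatomical-stats tables (comment header with a `ColHeaders`
line; whitespace-delimited rows) provide, for nine Brodmann areas (BA1, BA2,
BA3a, BA3b, BA4a, BA4p, BA6, BA44, BA45), surface area, gray volume, mean
thickness and thickness SD → 36 canonical columns `<region>.<metric>`. No
intracranial-volume correction is applied. The pairwise screen conventionally
uses the 27-column {area, vol, thick_avg} subset; the latent model uses all
36. Zero-variance columns are retained but flagged and excluded from
correlation/standardization.

## Pairwise screen

Pearson correlations for all morph × physio pairs (pairwise-complete on
missing data). The permutation null shuffles the subject rows of one block
jointly, 1000 times by default; p is the literal proportion of permuted |r| at
least as extreme as observed (two-sided; a one-sided mode and an add-one
corrected mode exist — the latter is used wherever downstream code takes logs
of p). BH-FDR is the standard step-up, applicable globally or per subgroup
panel. The "cluster" flag is a *reconstruction* of an under-described
published rule: per contiguous subgroup block, the density of significant
cells is compared to the median block density and flagged beyond 3 × raw MAD.
With few blocks or near-identical densities the raw MAD degenerates to 0 and
any deviation flags; at least 3 blocks are required.

## Sparse PLS

One component solves

    max_{u,v} u' X' Y v   s.t. ‖u‖₂ = ‖v‖₂ = 1, ‖u‖₁ ≤ c_u, ‖v‖₁ ≤ c_v,

on column-standardized blocks — the penalized-matrix-decomposition form of
sparse PLS. Budgets live in [1, √dim]: c = 1 is a one-hot vector, c = √dim
removes the constraint. The update alternates soft-threshold-and-normalize
steps from a deterministic start (leading right singular vector of X'Y),
stopping when the largest weight change is below 1e-6 or after 500 iterations
(non-convergence is flagged, not raised). The soft-threshold level that makes
the normalized vector's L1 norm exactly c is found in closed form by sorting
support candidates and solving the per-interval quadratic; a bisection solver
is retained as an independent cross-check and matches to 1e-6. Sign convention:
the largest-|v| entry is positive, with u flipped jointly — results are
bit-reproducible across runs. Deflation is by projection on both blocks
(X ← X − (Xu)u', Y ← Y − (Yv)v'), which zeroes the fitted direction and is
idempotent. Standardization (mean/SD) is always learned on training subjects
and applied to validation/holdout/external data; missing values are mean
imputed within the training fold.

## Multiple-holdout framework

Defaults: K = 10 outer splits with 20% holdouts (sizes round to the nearest
subject), M = 50 inner train/validation resplits (20% validation) inside each
optimization set, an 8 × 8 logarithmic budget grid over [1, √p] × [1, √q],
B = 1000 holdout permutations, two latent dimensions. One master seed fans out
deterministically to every stage.

Per grid point the model is fitted on the M inner training folds;
*generalizability* is the mean validation latent correlation and *stability*
the mean chance-corrected support overlap of the fold weight vectors
((|S_i∩S_j| − E)/(min − E) with E = |S_i||S_j|/p, averaged over pairs and
blocks; degenerate pairs contribute 0). The winner minimizes the unweighted
rank-sum of the two criteria, ties broken toward the sparser budget pair. The
tuned model is refitted on the full optimization set and scored on the
holdout; the permutation p shuffles the holdout pairing with fixed weights
(add-one corrected, two-sided). p-values are BH-adjusted across splits per
dimension. The global (omnibus) null — no split shows a true association — is
tested by default with a *joint* max-|r| permutation test: one global subject
relabelling per draw induces a coherent permutation of every split's holdout
pairing, and the omnibus statistic is the largest holdout |correlation|
across splits. Because overlapping splits make the K per-split p-values
positively dependent (measured pairwise correlation ≈ 0.1 on null cohorts),
the textbook Bonferroni rule (reject iff min p < α/K; available as
`omnibus="bonferroni"`) is an inequality rather than a level-α test and
measures conservative (type-I ≈ 3% pooled over 320 null replicates at
nominal 5%), whereas the joint test preserves that dependence in its null
and measures calibrated (3–4% over 440 null replicates; the small residual
traces to conditioning on weights trained from overlapping optimization
sets). The optimal
split is the BH-significant split with the best rank-sum of holdout
correlation and stability. The second dimension repeats
tune/evaluate on projection-deflated blocks within each split, reported but
not privileged. By construction nothing learned from data touches holdout
rows — asserted in tests by mutating holdout subjects and byte-comparing every
training artifact.

Two behaviours measured on planted cohorts (n = 100, p = q = 30, 5-sparse,
ρ = 0.7, noise SD 0.5) are worth knowing. First, the min-p omnibus rule is
conservative: with B = 200 permutations and 20-subject holdouts it rejects in
roughly three quarters of planted-effect replicates (and at the nominal ~5%
on null cohorts); larger B sharpens it. Second, the rank-sum tuning shows a
block asymmetry: budgets for the second-updated block (physio here) settle
near the oracle sparsity (median support Jaccard vs truth 0.8) while the
first block is allowed to run denser (median ≈ 0.6); with truth-informed
budgets both blocks recover their supports exactly, so the gap belongs to the
tuning criterion, not the estimator.

## Downstream statistics

**Partial correlations.** For the 5-variable table (both latent scores,
UPDRS-III, years since diagnosis, age) every pair is residualized on all
remaining variables (with intercept) and the residuals correlated; p-values
use the t distribution with n − 2 − k df and are BH-corrected over the 10
unique pairs. Collinear controls raise with the offending set named. Verified
against the closed 3-variable form to 1e-12 and against `pingouin.pcorr`.

**Stepwise AIC.** Bidirectional stepwise OLS from the intercept-only model:
at each step the single add or drop with the lowest AIC is accepted if it
improves, stopping at a local minimum, with a predictor cap of n/5.
Candidates are the optimal split's nonzero-weight features, each scaled by its
weight (raw-feature mode available). On strong-signal data the selected set
matches exhaustive best-subset AIC. Do note AIC's known liberality: under a
pure-noise null it admits a spurious predictor whenever t² > 2 (~16% per
candidate), so null models are near-empty rather than always empty.

**Cohort transfer.** A trained component is applied to an external cohort
using the *training* standardization (the external cohort contributes nothing
but its final correlation); features absent externally — e.g.
cortico-subcortical metrics in a cohort without basal-ganglia recordings —
have their weights dropped with a disclosure, and the transfer refuses if more
than half the trained nonzero weights are unavailable. Significance is a
fixed-weight permutation p.

## Synthetic generators

`simulate_oscillatory_channel` builds 1/f^slope background (spectral shaping
of white noise; stationary and slope-exact), per-band carriers under boxcar
burst envelopes (exact truth intervals), optional line tone and triangular
spike artifacts. Defaults: 60 s, 1 kHz, slope 1, background scale 0.05.
`simulate_coupled_channels` shares a band-limited source so the in-band MSC is
analytically mix²/(mix² + (1−mix)²). `simulate_feature_cohort` draws latent
scores (z, w) jointly Gaussian at ρ_true, plants equal-magnitude random-sign
sparse weights (unit L2), adds i.i.d. Gaussian feature noise (SD 0.5 by
default — about half the latent signal's per-feature scale), and generates
covariates with PD-surgery-typical marginals (age ≈ 64 ± 8, UPDRS-III
≈ 38 ± 12, duration ≈ 8 ± 4 years, ~26% female) optionally coupled linearly
to the latent scores. Everything is bit-reproducible from its seed.

What the generators do *not* emulate: volume conduction, nonstationary or
state-dependent dynamics, heavy-tailed or structured (correlated) feature
noise, site effects, and morphometric measurement error that correlates
across regions. Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated model, not performance on real
recordings.

## Problem sizes used in the shipped studies

The acceptance studies run at reduced-but-faithful sizes chosen once: 20
seeded channels for burst recovery; 100 windows for the coherence oracle; 20
planted-cohort replicates and 200 null replicates of the framework at K = 5,
M = 20, B = 200 (8 × 8 grid for recovery, 4 × 4 for the null calibration,
first dimension); 1000 random vectors for the BH oracle; 20 replicates of the
12-candidate stepwise oracle. The analysis scripts run the full defaults
(K = 10, M = 20–50, B = 1000, two dimensions) on a single 100-subject cohort.

## Known limitations

- The feature enumeration reproducing a published "92 features over five
  bands" is not recoverable from four bands and two named cortical pairs; the
  default is the 84-column enumeration above and counts are config-driven.
- The MAD cluster rule is a labelled reconstruction; its block partition is
  the canonical subgroup order and other readings exist.
- Burst durations are unbiased only near the 25% burst-time fraction (see
  above); comparisons of burst duration across subjects remain valid because
  the bias is a deterministic function of threshold mass, but absolute
  durations should not be over-interpreted.
- The correlation-maximizing (CCA) variant is a reserved flag
  (`fit_spls_component(..., variant="cca")` raises `NotImplementedError`);
  the covariance-maximizing sparse PLS is the primary and only estimator.
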
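# Methods

This note documents the models, the synthetic-cohort generator, the
numerical choices and the known limitations of `metabopredict`.

## The statistical model

### O-PLS / O-PLS-DA

The engine is single-response orthogonal projections to latent
structures. X is column-centered and, by default, unit-variance scaled
(options: `none`, `uv`, `pareto`); y is centered. For one response the
covariance direction w ∝ Xᵀy is invariant under orthogonal-component
deflation (since t_oᵀy = 0 exactly), so the fit is closed-form and
deterministic:

1. w = Xᵀy / ‖Xᵀy‖, t = Xw, p = Xᵀt / tᵀt;
2. per orthogonal component: w_o ∝ p − (wᵀp)w, t_o = Xw_o,
   p_o = Xᵀt_o / t_oᵀt_o, X ← X − t_o p_oᵀ;
3. the predictive component is refit on the filtered X; q = yᵀt / tᵀt.

If ‖w_o‖ < 1e-12 there is no orthogonal variation left; the loop stops
early and the model records the actual count. With one orthogonal
component the training predictions coincide with two-component PLS1 (the
classical equivalence), which the test suite uses as a second oracle next
to an independently coded NIPALS implementation.

Discriminant analysis dummy-codes a two-level factor as 0/1 by sorted
level name. `n_orth = 1` is the default: on this problem the dominant
X-variance (overall excretion level, latent disease severity) is largely
orthogonal to the extreme-vs-midgroup contrast, and filtering it is what
lets a single predictive component separate a class that pools both tails
of the severity axis.

### Cross-validation and Q²

`kfold_cv` uses seeded fold assignment (stratified by class for DA, with
a logged fallback to unstratified folds when a class is smaller than k),
pools PRESS over held-out predictions, and reports
Q² = 1 − PRESS/TSS with TSS about the full-sample mean (the chemometrics
convention; per-fold means would be a config switch away). k = 7 is the
default; for very small contrasts (minority class < k) the pipeline
switches to leave-one-out so every training fold still contains both
classes under any permutation of y.

### Permutation validation

Empirical p-values permute the response and recompute the full
cross-validated statistic, re-drawing CV folds inside every iteration —
the conservative choice, which also makes the observed statistic
exchangeable with the permuted ones under the null (the calibration tests
rely on this). The add-one convention
p = (1 + #{stat_perm ≥ stat_obs}) / (n_iter + 1) makes p = 0 impossible;
the smallest attainable value is 1/(n_iter+1). The test is one-sided
(large Q² = signal). The full-study default is 10,000 iterations; the
pipeline default is 999 so a complete run stays interactive, and the
suite uses 99–5,000.

### ROC

AUC is the midrank Mann-Whitney statistic on held-out cross-validated
predictive scores (ties count ½); the curve itself comes from
scikit-learn with no intermediate-point dropping, and trapezoidal
integration of that curve agrees with the rank statistic to 1e-12 (an
asserted invariant, not an approximation).

### Association map and screen

Spearman rho is the Pearson correlation of midranks, pairwise-complete,
flagged NaN when fewer than 3 pairs remain or a rank variance is zero.
Per-cell permutation p-values are two-sided on |rho| with the add-one
correction; each cell's generator is seeded by
`SeedSequence([master, i, j])`, so subsetting features or parallelizing
columns never shifts another cell's p-value (the permutation sample is
vectorized as one gather plus one matrix product). Masking is per-cell
p < α with no multiple-testing correction by default, matching the
heatmap convention of the field; a Benjamini-Hochberg mask is available
(`AssociationMatrix.fdr_mask`). The phenotype screen fits one
permutation-validated O-PLS regression per (timepoint, phenotype) pair
and skips zero-variance phenotypes with a note.

### Stratification

Upper rule: trait > mean + k·SD (sample SD, n−1 denominator), k = 2 by
default, applied to cumulative glycemia (CG, trapezoidal area under the
IP-GTT curve, mM·min) and body weight. Animals above both thresholds are
Ob-IGT; above the glycemia threshold only, L-IGT. The lower (LNG) rule is
not biologically sharp anywhere; this package's default labels an animal
LNG when both traits sit at or below the sample 10th percentile, which
makes the non-responder group an extreme tail comparable in size to the
other extreme groups — consistent with non-responders whose glycemia
resembles untreated controls. The rule applied is recorded verbatim in
every stratification output and is fully configurable. A zero SD in a
stratifying trait produces a warning (no upper exceedance), not an error.

## Preprocessing

**RSPA.** Specified operationally: per sample, the current segment is
shifted by the integer in [−max_shift, max_shift] that maximizes Pearson
correlation with the reference segment (exhaustive, vectorized over an
edge-padded sliding window; ties prefer the smaller |shift|); the segment
is then bisected at the reference's interior intensity minimum and the
procedure recurses until segments fall below `min_segment` (default 32
points; `max_shift` default 20; gain threshold default 0 = accept any
improvement). Shifted segments are edge-padded. The reference is the
sample with the highest mean correlation to all others (ties broken
lexicographically). A sample whose full-spectrum correlation to the
reference would decrease is reverted, so alignment never degrades the
dataset.

**PQN.** Negative intensities are floored at 0; the reference is the
column-wise median spectrum (or an explicit vector); the dilution
estimate is the median quotient over columns where the reference is
positive; the sample is divided by it. Two identifiability facts are
deliberately documented rather than hidden: (i) with the self-derived
median reference, dilutions are recoverable only up to one common factor,
so recovery tests compare after rescaling both sets by their geometric
means; (ii) the median-quotient estimator inherits biological variance —
with a 15-metabolite library in which most metabolites co-vary with the
disease driver, its error is ~10%. For this reason PQN runs on
full-resolution spectra (thousands of columns dominated by baseline and
unloaded resonances) *before* SRV, not on the handful of cluster
features, where the median quotient would absorb the shared biology and
bias every feature. The strict recovery bounds (exact up to the common
factor) hold when dilution is the only source of variation.

**Region exclusion** uses half-open [lo, hi) windows on the ppm axis;
defaults remove the water (4.5–5.0) and urea (5.4–6.2) regions.

## SRV features

The correlation landscape r_j is the Pearson correlation of consecutive
columns across samples (constant columns contribute 0); maximal runs with
r_j ≥ 0.9 covering ≥ 3 columns become clusters, so boundaries sit at
local minima of the landscape by construction. Features are per-sample
cluster means (sum optional), log-transformed with offset = 1% of the
positive median (recorded in the output). Clusters are annotated with the
library metabolite whose peak center lies in the cluster span, nearest
center to the span midpoint first, ties lexicographic; multiplet
metabolites (hippurate, PAG, choline) therefore contribute several
clusters that are redundant measurements of one concentration — analyses
that rank "marker metabolites" collapse clusters by label first.

A structural caveat: with exactly zero noise, Lorentzian tails make *all*
consecutive columns correlate near 1 (the line shape has infinite
support), so peak-boundary recovery is only defined relative to a noise
floor. Boundary-recovery tests therefore use planted correlated-block
fixtures where the truth is discrete; on realistic simulator output the
suite checks that every strong marker apex lands in a cluster labelled
with its metabolite.

## The synthetic cohort

The generator emulates the study design the pipeline targets: 50
isogenic animals, urine at days 0/1/2/20 of an HFD challenge, IP-GTT at
0/15/30/75 min, ~40 day-20 quantitative phenotypes (glycemia and
insulinemia curves with trapezoidal summaries, body weight and
composition, organ weights and ratios, feeding and behavioral traits).

Statistical backbone: one latent disease driver z ~ N(0,1) per animal
(a two-driver glycemia/adiposity switch exists for stratification
experiments). Baseline log-excretion of metabolite m is
log c_m = log(baseline_mean_m) + effect_size·loading_m·z + σ_m·ε,
with σ_m the metabolite's own CV if set, else the global
`conc_log_sd` = 0.25. Day-20 phenotypes are monotone in z plus
independent noise; body weight tracks its driver tightly (corr ≈ 0.93)
while cumulative glycemia is noisier (corr ≈ 0.63) — the latter value is
pinned by the calibration below.

Planted structure:

* **Markers.** TMAO is the primary positive marker (loading 0.9, CV
  0.15), followed by PAG (0.42), hippurate (0.40), DMA (0.33), choline
  (0.30) and MMA (0.26); TMA is weakly negative (−0.22). `effect_size`
  defaults to 0.5, calibrated once by Monte Carlo so the TMAO →
  cumulative-glycemia Spearman rho averages 0.6 across seeds.
* **Extreme responders.** The top-z animals are planted as Ob-IGT (4% of
  the cohort) and L-IGT (4%); the bottom-z animals (8%) as LNG
  non-responders with control-like glycemia and no weight gain.
  IGT animals receive glycemia (and Ob-IGT also body-weight) boosts
  sized to exceed the 2-SD thresholds; all planted extremes additionally
  carry an "extreme responder" metabotype shift on TCA-cycle metabolites
  (citrate, 2-oxoglutarate, fumarate), scaled by `effect_size` so that a
  zero effect size yields a completely null metabolome. This shared
  signature is what makes the extreme-vs-midgroup contrast (which pools
  both tails of z) linearly separable, mirroring the observation that
  extreme responders are metabolically distinct in kind, not just in
  degree.
* **Instrumental effects.** Per-sample multiplicative dilution
  exp(N(0, 0.3)), integer chemical-shift jitter uniform on ±4 points
  (edge-padded, no wrap-around), additive Gaussian noise (SD 0.1–0.3 of
  apex units; default 0.3, an apex SNR of ~10 for the weakest library
  peak and ~180 for the strongest), and a smooth per-sample baseline from
  three random low-frequency cosines.

All randomness flows from one seed through a `SeedSequence` tree:
identical configuration gives a bit-identical cohort. The ground truth
(z, true concentrations, dilutions, jitters, planted groups, and the
labels obtained by applying the 2-SD rule to the noiseless phenotypes)
is returned and written alongside the observables.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no raw FIDs, phasing, water suppression or
baseline-correction artifacts; Lorentzian singlets/multiplets without
J-coupling fine structure or pH-dependent shift drift (jitter is a rigid
per-spectrum shift, not peak-specific); log-normal, mostly independent
concentration noise rather than a realistic urinary correlation network;
no litter/cage effects; phenotype noise Gaussian on the trait scale
(truncated at zero for weights and counts). Success here demonstrates the
statistical machinery, not instrument-level robustness.

## Problem sizes in the test and acceptance suites

Monte-Carlo checks are desk-scaled: null calibration of the Q²
permutation test uses 200 replicate cohorts at 99 iterations on the
ground-truth day-0 concentration matrix (the quantity under test —
calibration under X ⊥ y — does not depend on the spectral stage, and the
concentration matrix *is* simulator output); association-null
calibration uses 20 cohorts at 199 iterations per cell; signal-recovery
checks run the full spectral pipeline on 20 seeds at the default cohort
size; enumeration oracles run at n = 5 (120 permutations) and n = 6 (720
permutations, leave-one-out CV so the statistic is a deterministic
function of the permuted response). The full suite runs in about a
minute on one CPU; `scripts/acceptance.py` in ~15 s.

## Reproducibility

One master seed per pipeline run; per-stage seeds are derived by mixing
CRC32(stage name) into a `SeedSequence`, so toggling one stage never
perturbs another's randomness. Reports repeat exactly for identical
config + seed in a fixed floating-point environment (x86-64, IEEE-754
double, numpy ≥ 2); wall-clock stage timings in `report.json` are the
only non-reproducible fields.

## Known limitations

* The RSPA segment-shift search is greedy per segment; pathological
  spectra could in principle improve segment-wise while degrading
  globally — the per-sample revert guard bounds the damage but does not
  search alternatives.
* PQN assumes a majority of stable columns; cohorts where most of the
  spectrum co-varies with the outcome violate this (see above), which is
  why feature-level PQN is not offered as a default.
* The LNG/midgroup boundary is a convention, not an estimate; all
  downstream contrasts involving LNG inherit it.
* Permutation p-values are bounded below by 1/(n_iter+1); at the
  pipeline default (999) the floor is 0.001.
* Small contrasts (n < 10) give honest but noisy Q²/AUC; leave-one-out
  CV keeps them defined, nothing makes them well-powered.
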
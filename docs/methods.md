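# Methods

## Model and estimation conventions

A clock is a sparse linear map from CpG methylation fractions (beta values in
[0, 1]) to age in years. Fitting follows the conventions of penalized
regression as implemented in the R package this family of clocks is usually
built with:

- **Objective.** With mixing parameter `alpha` in [0, 1] and penalty `lambda`,
  minimize `(1/2n)·Σ(y − b0 − x·b)² + lambda·(alpha·‖b‖₁ + (1−alpha)/2·‖b‖₂²)`.
  The intercept is never penalized.
- **Standardization.** Predictors are centered and scaled to unit *population*
  standard deviation inside the optimizer (recomputed on each CV training
  fold — the held-out fold never leaks into the scaling); returned
  coefficients are back-transformed so fitted clocks apply directly to raw
  betas. Constant predictors get scale 1 and necessarily zero coefficients.
- **Penalty path.** 100 geometric values from
  `lambda_max = max_j |⟨x̃_j, y − ȳ⟩| / (n·max(alpha, 1e-3))` down to
  `lambda_max · 1e-4` (`1e-2` for the logistic screen, whose deviance
  saturates earlier). `lambda_max` is the smallest penalty at which every
  coefficient is zero; the `max(alpha, 1e-3)` floor keeps ridge-like paths
  finite.
- **Penalty selection.** K-fold (default K = 10) cross-validated mean squared
  error, minimized over the path ("lambda-min"). Ties — including numerical
  ties within 1e-10 relative — resolve to the largest penalty. A
  one-standard-error rule (`penalty_selection="1se"`) is available; clock
  fits default to lambda-min because the grid-selection step already guards
  against overparametrization (below).
- **Solver.** Coordinate descent (scikit-learn's `enet_path`) at default
  tolerance 1e-4 with 3000 iterations; oracle-grade comparisons in the test
  suite pass tighter tolerances explicitly. Pure ridge (`alpha = 0`) is
  solved exactly per penalty via SVD rather than coordinate descent.
- **No age transformation.** Regression is on untransformed years. Negative
  predictions are reported as-is; they are meaningful for fetal/neonatal
  samples.

## Pipeline defaults

| Parameter | Default | Meaning |
|---|---|---|
| `alpha` grid | 0.1 … 0.9 step 0.1 | lasso/ridge mixing sweep |
| filter thresholds | 0, 10, 20, 30 | min. samples with detection p < .05 per CpG (0 = no filter) |
| significance level | 0.05, strict `<` | detection-p call |
| `n_folds` | 10 | internal CV folds |
| `medae_tolerance` | 0.05 y | parsimony band in model selection |
| outlier `z_cut` | 2.0 | SDs below mean inter-array correlation |
| bootstrap | 10 000 resamples | percentile CI on period means |

**Grid evaluation and selection.** Candidate clocks on the
(alpha × threshold) grid are scored by *in-sample* metrics; LOOCV is the
confirmation step, run at the chosen configuration. Among candidates whose
median absolute error is within `medae_tolerance` years of the grid minimum,
the one with fewest CpG terms wins; ties break toward larger alpha, then
larger filter threshold. This encodes the preference for the most parsimonious
near-optimal model and reproduces the pattern that small alphas admit
extraneous CpGs which flatter the in-sample fit.

**LOOCV.** Each held-out fit refilters probes on the remaining n − 1 samples
(no leakage); `refilter=False` reproduces the optimistic variant that reuses
the whole-set filter. Training samples are ordered lexicographically by id
before fold assignment, so per-sample held-out predictions are invariant to
input order at a fixed seed.

**Confounder screen.** Binary nuisance labels (subspecies, tissue source;
"1" marks the group of concern) are screened with a binomial elastic net at
alpha 0.5, stratified K-fold CV on binomial deviance. The screen defaults to
the **one-standard-error** penalty rule rather than lambda-min: on
permutation-null labels the deviance-minimizing penalty admits a handful of
noise CpGs in roughly half of draws (the reference R implementation behaves
identically), while the 1-SE rule keeps the null screen mostly empty and
still recovers genuinely separating probes. A clock passes the confounding
check when its CpG set is disjoint from every diagnostic set.

**Rank tests.** The two-sample statistic W follows the Mann–Whitney U
convention (rank sum of the first sample minus `n_x(n_x+1)/2` on midranks),
matching the convention of the R function such W values are reported from.
Exact nulls are used when tie-free and `n_x·n_y ≤ 400` (signed-rank: up to 20
nonzero differences); with ties, forced-exact mode enumerates all group
assignments / sign patterns on midranks; otherwise a normal approximation
with midrank tie correction and continuity correction applies. Two-sided
exact p is `min(1, 2·min(lower tail, upper tail))`. Zero paired differences
are dropped; all-zero differences give the degenerate V = 0, p = 1.

**Probe screening.** Per-CpG Pearson correlations with age use
pairwise-complete observations and two-sided t-tests on n − 2 df; probes with
fewer than 3 observations or zero variance are excluded (r undefined, never
0). No multiple-testing correction is applied to per-CpG p-values — summaries
report raw significance counts. |r| bins are half-open [a, b) with the last
bin closed at 1.0; boundary values belong to the upper bin.

**Outlier flagging.** The visual dendrogram call used in practice is replaced
by a reproducible rule: flag samples whose mean inter-array Pearson
correlation (on complete-case probes) falls more than `z_cut` SD below the
across-sample mean; the average-linkage hierarchy on distance 1 − r is kept
in the report for manual review.

**Missing data.** Missing betas are storable; training drops probes with any
missing value in the training set (the simplest defensible rule — no
imputation). At prediction time a missing clock probe is governed by an
explicit policy: `error` (default) or `skip_sample`.

## Synthetic data

The generator emulates normalized array betas: informative CpGs follow
`inv_logit(a_j + s_j·age)` plus Gaussian beta-scale noise (clipping to [0, 1]
is a safety net, not the mechanism), with slopes `s_j` positive for a
configurable share of sites and magnitudes drawn in [0.75, 1.25] × 0.1
logit/year — about 2 logits across a 0.25–20-year age span, comfortably
detectable at the default noise SD 0.02. Background probes sit at uniform
baselines; detection failures are independent per measurement at rate 0.05;
an optional batch effect shifts a chosen set of background probes in one
binary group (batch probes are given baseline headroom so the shift survives
clipping). Serial fixtures reuse the same probe parameters and space repeat
samples of an individual by a fixed gap with consistent collection dates.

Defaults (n = 60 samples, 2000 probes, 8 informative CpGs, noise SD 0.02)
define the synthetic study condition used by the recovery tests: a candidate
grid over alphas {0.1, 0.3, 0.5, 0.7, 0.9} × thresholds {0, 10} on 60
training samples, with 30 held-out samples for accuracy, and LOOCV at
alpha 0.9. The shifted-cohort power simulation uses period means 8.5 vs 7.4
years with within-period SD 1.5 years and n = 40 per period — the dispersion
implied by reported period means and their 95% CIs at plausible period sample
sizes.

What the generator does **not** emulate: genomic autocorrelation of
methylation, array probe chemistry, realistic (non-uniform) age
distributions, correlated probe-level detection failure, or measurement
error that depends on the beta value. Passing recovery tests therefore
demonstrate correctness of the pipeline's statistics and optimization, not
field performance on real arrays.

## Known limitations

- Alpha and the filter threshold are selected on the same grid that reports
  the metrics (no nested double-CV); LOOCV confirms but does not re-select.
- The packaged published clock is applied exactly as printed; it assumes
  normalized betas from the same array platform and cannot be re-derived
  here without the original training arrays.
- No normalization, batch correction, or genomic annotation of probes is
  provided; the artifact consumes normalized betas.
- In-sample candidate metrics are optimistic by construction; LOOCV error is
  the honest figure and is never smaller on the same data.
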
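# Methods note

This note records the scientific and numerical choices behind `nmrfib`:
what each stage assumes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Study structure

Four kidney groups from a unilateral-ureteral-obstruction (UUO) experiment:
A = obstructed (UUO left), B = contralateral (UUO right), C = sham left,
D = sham right; 11 UUO and 9 sham animals, two kidney samples per animal.
Serum chemistry (Scr, BUN, ALB) is per animal; histology grades (TIS 0–3,
ICD % area) are recorded per animal for the graded kidney.

## Preprocessing

Bucketing tiles δ 0.78–9.66 with half-open 0.01 ppm intervals
[left, left + w): 888 raw buckets. A bucket is dropped when it intersects
the *open* residual-water interval (4.68, 5.23) at all — the conservative
reading, since partial water contamination is still contamination — which
removes exactly 55 buckets and leaves 833. A bucket merely touching a
boundary point survives.

Bucket values are rectangle-rule integrals (sum of point intensities times
the point spacing) rather than mean intensities, so values are stable under
a change of digital resolution. Normalisation divides each sample's row by
its tissue weight in grams; nothing else (no probabilistic-quotient or
total-area step) is applied, matching the study's stated procedure. The
normalisation is guarded against double application.

Relative contents integrate each metabolite's declared quantification
window and divide by tissue weight. The packaged 14-metabolite assignment
library is synthetic in the strict sense: the original supplementary
assignment table is unavailable, so canonical literature shifts are used
(lactate CH₃ doublet 1.33 ppm, TMAO singlet 3.27 ppm, 3-hydroxybutyrate
doublet 1.20 ppm, …) with pairwise-disjoint windows outside the water
region. Every contracted quantity downstream (directions, α, ADF,
correlation signs) depends on relative contents, not on the absolute truth
of the shifts.

## Chemometrics

All latent-variable models are implemented directly (no wrapped
chemometrics library); scikit-learn appears only as an independent oracle
in the test suite.

* **PCA**: SVD of the mean-centered matrix; explained-variance fractions
  are eigenvalue shares of the total centered variance.
* **PLS-DA**: class membership coded +1/−1 (alphabetically first class
  positive, recorded in the model); NIPALS with deflation, which is exact
  and non-iterative for a single response.
* **OPLS-DA**: orthogonal-signal removal — each orthogonal component's
  weight is the X-loading minus its projection on the predictive weight —
  followed by a single predictive component on the deflated matrix.
  Predictive scores are orthogonal to every orthogonal score (enforced to
  1e-8 in tests); `n_ortho = 0` reduces exactly to 1-component PLS-DA.
* **Component signs** are fixed so the largest-magnitude loading entry is
  positive; the sign flip is applied jointly to weights, scores, loadings
  and y-loadings, leaving fitted values invariant.
* **Scaling**: the library default is mean-centering only. Unit-variance
  (UV) and Pareto scaling sit behind the `scaling` flag. The *pipeline's*
  bucket-level screening model defaults to UV: with center-only weights
  (w ∝ cov(x, y)) the model is dominated by high-abundance metabolites and
  low-abundance ones (allantoin at ~0.02 relative units, uracil at ~0.06)
  can never reach VIP ≥ 1 regardless of effect size, which would defeat the
  abundance-blind intent of the VIP cut. UV scaling makes bucket weights
  reflect correlation with class rather than raw variance.
* **Q²**: 1 − PRESS/SSY over class-stratified k-fold cross-validation
  (default 7 folds, a widely used chemometrics-software convention, not a
  study fact; seeded and deterministic). Each fold refits the whole
  procedure — centering, scaling, orthogonal removal — on the training
  block only. Folds are assigned round-robin within class after a seeded
  shuffle, so no training block can lose a class while both classes have
  at least two members.
* **Permutation test** (default 200 relabelings): records R²Y and Q² of
  each permuted model against |corr(y_perm, y)|; draws identical to the
  original labelling are redrawn. The Q² intercept comes from a
  least-squares line through the permuted points plus the original at
  |corr| = 1. The model passes when (intercept < 0 or every permuted Q²
  lies below the original) *and* the original Q² is positive. The last
  guard is deliberate: a model with no cross-validated predictivity can
  still produce a negative intercept (the whole permuted cloud sits below
  zero), and certifying it would make the test useless as an over-fit
  check. With the guard, the measured false-positive rate on pure-noise
  data is 4/50 runs at 200 permutations.
* **CV-ANOVA**: F = ((SSY − PRESS)/df₁)/(PRESS/df₂) with df₁ = number of
  fitted components (predictive + orthogonal) and df₂ = N − df₁ − 1;
  p from the F distribution. PRESS ≥ SSY returns p = 1 (no evidence), not
  an error.
* **VIP** uses predictive components only (for OPLS-DA, the single
  predictive component), normalised weights, and component SSY = q²·t′t;
  Σ VIP² = number of variables holds identically.

## Screening

Differential metabolites must satisfy a conjunction: VIP ≥ 1.0,
|p(corr)| ≥ 0.5 and Welch p < 0.05 for A vs C. The VIP and p(corr) cuts are
field conventions (no thresholds were stated by the study) and are
configurable. The Welch (unequal-variance) t-test is used as the safer
two-group default; for two groups the 95%-confidence ANOVA cited alongside
it is the equal-variance special case (F = t²). p-values are reported raw —
no multiple-testing correction, matching the original report — with
Benjamini–Hochberg available to callers via `statsmodels` if desired.

Bucket-level model evidence is mapped to metabolites by taking the
highest-VIP surviving bucket inside each metabolite's quantification
window; its VIP, p(corr) and coefficient become the metabolite's criteria.
Directions (up/down) report sign(mean_A − mean_C), with a relative epsilon
(1e-9) flagging flat contrasts.

## Fibrosis index

α = (X_B − X_C)/(X_A − X_C) per metabolite, %ADF = 100 × mean |α|. The ADF
is computed as the mean of absolute change rates because that is the only
reading consistent with the published per-metabolite α column and summary
value (the printed formula is typographically garbled). Recomputing from
the packaged (rounded) group means gives 26.1% against the published
25.5% — the original was evidently computed from unrounded data — and the
per-metabolite α column is reproduced to ±0.01 everywhere, exactly at
three decimals for lactate, methionine, TMAO and valine.

Denominators below 1e-9 × max(|X_A|, |X_C|, 1) exclude the metabolite with
a recorded reason rather than propagating NaN. Both a mean-table entry
point (auditable against a printed table) and a sample-level entry point
(group means computed from data) are provided. α is unit-free: common
rescaling of a metabolite's three means cancels, so quantification-window
coverage factors drop out.

## Correlation report

Pearson r per (metabolite, endpoint); two-sided p from the exact
t-transform with n − 2 df; stars *, **, *** at p < 0.05, 0.01, 0.001 with
boundary values falling in the weaker category. Zero-variance inputs flag
the cell undefined. The default sample-to-endpoint join uses left kidneys
only (obstructed vs sham-left): with both kidneys pooled, a metabolite that
moves oppositely in the two UUO kidneys (adenosine: down in A, up in B) has
a near-zero pooled correlation with severity and an unstable sign, while
the left-only contrast is stable; a `both` mode is provided. The biplot
uses two-component NIPALS PLS2 (UV-scaled blocks) and returns sample
scores, metabolite weights and endpoint loadings on a common basis.

## Synthetic-data generator

The generator's defaults are the study conditions: 11 UUO / 9 sham
animals, group-mean relative contents from the packaged reference table
(group D defaults to C, since the sham left/right difference is
negligible), tissue weights B = 1.67 ± 0.23 g and D = 1.18 ± 0.09 g as
published, A = 2.20 ± 0.30 g (hydronephrotic enlargement) and
C = 1.18 ± 0.09 g as package assumptions.

A per-animal latent severity s (UUO ~ N(1, 0.12) clipped to ±3 sd, sham 0)
interpolates each kidney's target mean between the sham baseline and its
group mean: target = C + s·(G − C). Both kidneys of an animal share one
severity, so group-mean ratios — hence α and ADF — are preserved in
expectation and exactly in the vanishing-dispersion limit. Concentrations
are log-normal around the target with a mean-preserving parametrisation at
cv = 0.15; no within-group dispersions were published, so the cv is a free
parameter chosen to give clear but not trivial group separation
(PCA-visible clustering, Q² well below 1). Endpoints are affine in
severity (Scr 35 + 45s µmol/L, BUN 5.5 + 9s mmol/L, ALB 38 − 7s g/L,
TIS 0.1 + 2.6s clipped to [0, 3], ICD 3 + 45s % clipped to [0, 100]) with
Gaussian noise of 8% of the slope; baselines are physiologically plausible
rat values chosen by the package, since the raw clinical table is not
available.

Spectra are sums of unit-area Lorentzian peaks (FWHM 0.003 ppm) on a
0.78–9.66 ppm axis at 0.001 ppm steps (10 points per bucket — a balance of
fidelity and test speed), scaled by tissue weight so that weight
normalisation recovers per-gram contents, plus Gaussian noise at 1% of the
median peak height and a residual-water hump confined to the excluded
window.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about real data: J-coupling multiplet structure,
pH-driven peak-position variation, baseline drift and phasing artefacts,
peak overlap beyond Lorentzian tails, and any biology outside the
severity-interpolation model (in particular, a metabolite whose direction
contradicts its published group means, as the published phenylalanine
correlation row does, cannot be reproduced by a generator faithful to
those means; the sign-concordance contract is ≥ 0.9, not 1.0, for exactly
that reason).

## Determinism and problem sizes

Every stochastic step (simulation, fold assignment, permutations) draws
from `numpy.random.default_rng` seeded from the run seed; identical
configs produce byte-identical tables. Default problem sizes — 40 spectra
of 8881 points, a 20 × 833 model matrix, 200 permutations with 7-fold CV —
run the full pipeline in a few seconds; the test suite's Monte-Carlo
checks (50-seed null calibration of the permutation test) use reduced
24 × 30 matrices, sizes chosen so the whole suite stays quick while the
sampling error of the checked rates remains small.

## Known limitations

* Relative quantification integrates fixed windows; it is linear in
  concentration only up to far Lorentzian tail leakage (~1e-6 relative at
  multi-ppm separation, ~2% between close neighbours such as the valine
  0.99 doublet and the leucine window).
* The real study's model statistics (R² = 0.952, Q² = 0.911, PC1 56.8%)
  depend on the unavailable instrument spectra and are report-format
  examples here, not reproduction targets.
* Multi-class (> 2 group) discriminant models, O2PLS and automated
  component-number selection are out of scope; figures are left to the
  caller (all plot-ready tables are produced).
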
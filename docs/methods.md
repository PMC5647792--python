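# Methods

`lipidq` implements a complete analysis chain for untargeted plasma
lipidomics feature tables from a case/control cohort design with
interspersed pooled-QC injections, together with a synthetic-cohort
generator that carries ground truth for every claim the pipeline makes.
This note records the models, the defaults and why they were chosen,
and what the synthetic data does and does not emulate.

## The data model

A run is a features × injections intensity grid. Each feature carries
m/z (Da), retention time (min) and ion mode; each injection carries a
role (study or pooled QC), group (healthy/disease), batch and run-order
slot. Positive- and negative-mode tables are processed independently
end to end. Missing cells are explicit `NaN`, never zero: zeros would
corrupt CVs and every log-scale step. Whether an on-disk `0` or a blank
means "missing" is an explicit reader flag (`missing_policy`), because
feature-extraction exports differ and guessing silently is worse than
asking.

## QC-driven feature cleaning

The pooled QC is an aliquot mixture of all study samples, injected
periodically; because its expected composition is constant, its
variance per feature measures pure technical noise. The cleaning stages
run in a fixed order — detection filter → kNN imputation → drift
correction → batch adjustment → QC-RSD filter → SNR clean → mean-shift
clean — with conservation enforced at every stage (input = removed +
retained).

* **Detection**: a feature is removed iff detected in strictly less
  than 50% of QC injections or strictly less than 20% of study
  injections. Study detection rate is computed over study injections
  only (the QC columns carry no information about cohort prevalence).
* **Imputation**: k-nearest-neighbour by feature (k = 10, the common
  choice in metabolomics preprocessing, configurable). Nearness is
  plain Euclidean distance between feature rows on the log2 scale over
  mutually observed injections; the imputed cell is the mean of the k
  nearest features' raw values in that injection, restricted to
  neighbours observed there. Imputing a complete table is the identity,
  and imputed values are bounded by the neighbours' values at that
  injection.
* **QC-RSD filter**: retain iff QC RSD (100 × sd/mean over QCs, sample
  SD) is strictly below 30%. The strictness at exactly 30.000…% is a
  measure-zero boundary; the threshold is configurable.
* **SNR clean**: remove iff sd(study)/sd(QC) < 1 — a feature whose
  biological spread is smaller than its technical spread is noise. A
  zero QC SD leaves SNR undefined; such features are retained and
  flagged rather than silently judged.
* **Mean-shift clean**: remove iff |mean(QC) − mean(study)| exceeds
  3 × sd(study) (strict); the pooled QC no longer represents the cohort
  for that feature.

## Drift correction (QC-robust spline)

Per feature, log2 QC intensity is regressed on injection order with a
cubic smoothing spline; the penalty is chosen by leave-one-out error
over a fixed grid (run order rescaled to [0, 1], λ ∈ 10⁻⁵…1, six
values). Every injection is then divided by curve(order)/reference,
with the reference the median QC intensity, so a flat fit is exactly
the identity and positivity is preserved (the curve is an exponentiated
log2 fit). Features with fewer than 4 observed QCs fall back to a
least-squares line; with fewer than 2 they are left uncorrected and
flagged. QC and study injections are corrected identically.

## Batch adjustment (parametric empirical Bayes)

Location/scale batch adjustment on the log2 scale: per-feature
standardization against the weighted grand mean and pooled residual
variance, per-batch means and variances shrunk across features toward
parametric priors (normal for locations, inverse-gamma for scales,
moment-matched), then adjustment back to the grand mean/pooled
variance. No covariates enter the model matrix; a `mean_only` switch
skips the scale adjustment for tiny batches. QC injections participate
in the fit — they carry batch signal like any other injection. A single
batch is returned unchanged; a batch with one injection is an error
naming the batch. The implementation is cross-checked in the test suite
against an independent implementation of the same estimator
(`scanpy.pp.combat`) to 2×10⁻³ on the log2 scale; residual differences
are iteration-convergence tolerance. Note the shrinkage keeps roughly
half of each batch-mean's sampling noise when batches are truly
homogeneous — the adjustment converges to a no-op only as batch sizes
grow.

## Scaling, PCA, PLS-DA

Intensities are log2-transformed, column-centred and Pareto-scaled
(divide by √SD): heavy lipid features are tempered without flattening
everything to unit variance. PCA is by SVD with a deterministic sign
convention (largest-magnitude loading positive) and is used as a run
diagnostic: pooled QCs must cluster tighter than study samples.

The discriminant model is two-class PLS (NIPALS, single response,
y coded 0/1 and centred; X and y deflated per component). Defaults:
A = 2 components, the convention for score plots and the reported
R²Y/Q².

* **R²Y** = 1 − RSS/TSS of the centred class code, in fit.
* **Q²** = 1 − PRESS/TSS from stratified 7-fold cross-validation;
  held-out predictions use the training fold's y-mean and — critically
  — Pareto scaling refit inside each training fold, so held-out
  injections never leak into the centering.
* **VIP**: VIP_j = √(p · Σ_a SSY_a w²_aj / Σ_a SSY_a) with
  SSY_a = c²_a t_aᵀt_a; the mean of VIP² over features is exactly 1,
  which the tests assert as an algebraic identity.
* **Permutation validation**: class labels are permuted (default 200
  times), R²Y and Q² recomputed, and empirical
  p = (1 + #{null ≥ observed})/(n_perm + 1).

## Univariate testing and selection

Per feature: two-sided unpaired Wilcoxon/Mann–Whitney (exact
enumeration when the combined n ≤ 20 with no ties, otherwise the normal
approximation with tie and continuity corrections), Benjamini–Hochberg
step-up adjustment, and the disease/healthy ratio of raw-scale group
means computed on normalized intensities (arithmetic means — the metaX
convention; a geometric-mean variant is a config switch). A feature is
selected as differential iff VIP ≥ 1 (inclusive) and q < 0.05 (strict).

## ROC and biomarker panels

Univariate AUC uses the Mann–Whitney identity with ties counting ½ and
a DeLong 95% CI (bootstrap CI available by argument). Scores are
auto-oriented so AUC ≥ 0.5, with the orientation recorded — except for
classifier probabilities, which carry their own direction and are
deliberately not flipped (flipping would bias null panel AUCs upward).

Panel selection: a stratified 2/3 training split; within it, features
are ranked by mean random-forest impurity importance over 7 stratified
folds; the top 10 form the panel; the held-out third is touched exactly
once, to compute the test AUC of a forest trained on the full training
split restricted to the panel. Forest defaults: 500 trees, sklearn
default feature subsampling, seeded. Panel discrimination is reported
as the ROC of out-of-fold predicted probabilities. Out-of-fold scores
are held-out, so they sit slightly below in-sample rank AUCs — the test
suite checks consistency, not equality.

## Lipid annotation

Monoisotopic masses are computed from molecular formulas with a fixed
most-abundant-isotope constant table (¹H 1.00782503, ¹²C 12 exact,
¹⁴N 14.00307401, ¹⁶O 15.99491462, ³¹P 30.97376200, ³²S 31.97207117);
this reproduces the reference neutral masses of the identified
LysoPC/PC/PI species to 6 decimals and agrees with `pyteomics` to
10⁻⁵ Da. Adducts: M+H = +1.00727646 (proton), M−H = −1.00727646,
M−CH3 = −15.0234751 (methyl radical; a config switch adds the electron
mass for the demethylated-anion convention, which is genuinely
ambiguous in practice). Mass error is signed ppm against the
theoretical m/z; the MS1 tolerance defaults to 10 ppm.

A candidate matches a feature iff some adduct valid in the feature's
ion mode is within tolerance AND the retention time falls inside the
candidate class's window. Default windows for a CSH C18 gradient
(LysoPC 0.7–2.2 min, PC 6.7–7.6, PA 5.6–6.6, PI 4.5–7.3) are derived
from observed elution of identified species, padded ±0.3 min, and fully
user-overridable — elution windows are gradient-specific and should be
recalibrated per method. Diagnostic fragments per class: phosphocholine
184.0733 (PC/LysoPC, positive), the demethylated [M−CH3]⁻ ion
(PC/LysoPC, negative), dehydrated inositol phosphate 241.0119 (PI,
negative), and fatty-acyl carboxylate anions computed from the sn
chains (e.g. 16:0 → 255.23295). Identification levels: 1 requires an
authentic-standard/curated MS2 match, 2 a theoretical-fragment match or
MS1 + class-consistent RT, 3 otherwise.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults set to the study conditions: 45 disease vs 45 healthy
subjects; a pooled QC every 10 study injections plus leading and
trailing QCs (the conventional design when the true run order is not
available); per-feature log-normal baselines with log2 means uniform in
[14, 22]; QC replicate noise calibrated so QC RSD ≈ 10%
(mean-preserving log-normal, σ² = ln(1 + CV²)); between-subject
biological CV 25% on top for study samples — a realistic
between-subject spread for plasma lipid species; 2 contiguous batches
with additive per-batch-per-feature log2 offsets (SD 0.3, the ComBat
model); multiplicative run-order drift from a rising half-cosine kernel
with peak-to-trough range equal to the amplitude (default 0.5),
jittered per feature in [0.5, 1]× so the drift is not rank-one; 2% MCAR
missingness plus intensity-dependent deletion below each feature's 15th
percentile; and 5% "noise" features whose study-sample spread is
constructed ~2.5× below their QC spread.

Differential features (default 10%) are spiked with disease/healthy
ratios whose bounds default to [0.37, 1.62], the span of reported
differential lipids. The magnitude of the log-ratio is drawn uniform
between log(1.25) and the bound, with random sign: a "differential"
feature with a ratio of ~1 would be a contradiction in its own truth
label, and reported differential lipid ratios are in practice bounded
away from unity (the weakest here is 1.10-fold). The 1.25 floor is the
smallest change conventionally considered biologically meaningful in
this setting.

What the generator does **not** emulate: chromatographic peak shapes,
isotope envelopes, co-eluting isomers, correlated features (each
feature is drawn independently), heavy-tailed outlier injections, and
m/z–RT structure tied to real lipid classes (feature m/z and RT are
uniform draws). Passing recovery tests therefore demonstrates that the
statistics behave correctly under the assumed noise model — not that
the pipeline is robust to every pathology of real LC-MS data.

## Numerical and sizing choices

* All randomness flows through seeds; a master seed fans out to
  per-stage seeds via CRC32 of the stage name, so optional stages can
  be reordered without reshuffling others. Outputs are bit-reproducible
  for a fixed seed.
* Degenerate inputs fail loudly: zero-variance features at scaling,
  single-class labels at PLS-DA/ROC, single-injection batches at
  adjustment, features with no observed values at imputation.
* Statistical checks in the test suite use deliberately modest problem
  sizes — 120–200 features, 50 null datasets, 50 permutations, 5 seeds,
  100–200 trees — chosen once as the smallest scales at which the
  Monte-Carlo error bands in the assertions are meaningful.
* The null-calibration checks generate cohorts without drift/batch/
  missingness artifacts so they measure the selection rule itself, not
  the normalization stack (which has its own dedicated tests).

## Known limitations

* The drift model corrects each feature independently; shared-drift
  pooling (borrowing strength across features) is not implemented.
* ComBat here is parametric only; the non-parametric variant and
  covariate-adjusted model matrices are out of scope.
* PLS-DA is strictly two-class; OPLS-DA and multi-class extensions are
  not provided.
* Annotation is MS1 + rules; no in-silico fragmentation, isotope-pattern
  scoring, or spectral-library parsing.
* Positive-mode printed mass errors in the reference material are not
  exactly reproducible from any standard M+H convention (the
  computation base of the original software is ambiguous); negative
  mode [M−H]⁻ errors reproduce to 0.02 ppm.
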
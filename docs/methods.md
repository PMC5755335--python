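# Methods

## Problem setting

Targeted serum metabolomics (Biocrates-kit-style FIA-MS/MS panels) yields a
wide concentration table — roughly 160 metabolites in a handful of chemical
classes, quantified in µM — for cohorts of a few dozen samples per group.
`crcmet` implements the full modelling chain used to turn such tables into a
validated diagnostic classifier for colorectal neoplasia: quality gating,
normalization, OPLS-DA with VIP-based signature refinement, cross-validated
and permutation-based validity checks, multi-platform fusion, and external
validation. Because no patient-level cohort is publicly deposited, the
package ships a synthetic-data generator that emulates the study conditions
with known ground truth, so every stage is testable end to end.

## Input gates

**QC coefficient of variation.** Per metabolite, CoV = sd/mean over the QC
replicates, with the sample (n−1) standard deviation — QC sets are small,
and the n−1 form is the conservative choice. Metabolites with CoV > 0.25
(default) are dropped; metabolites whose QC values are entirely missing are
flagged and dropped rather than silently kept. CoV is scale-free, so the
gate is invariant to unit changes.

**Limit of detection.** The LOD rule is operationalized as a detected-
fraction threshold: a metabolite must be non-missing in at least
`min_detect_fraction` (default 0.5) of samples. No numeric LOD
concentration is assumed; censoring is whatever the upstream quantification
reported as missing (`<LOD`, `NA`, `ND`, empty — the dialect is
configurable).

**Imputation.** Remaining missing cells are filled with the minimum
observed value. The default is the per-metabolite minimum, which preserves
each metabolite's scale; a table-global minimum is selectable for the
literal "minimum value in the dataset" reading. Imputation never alters
observed cells and is idempotent.

## Transformation chain

Order of operations: median fold-change normalization on the raw
concentration scale, then natural-log transform, then autoscaling. Ratios
to a reference profile are only meaningful on the raw scale, which fixes
the normalization ahead of the log step.

**Median fold-change normalization** (the probabilistic-quotient family):
the reference profile is the per-metabolite median over training samples;
each sample's dilution factor is the median over metabolites of
value/reference, and the sample is divided by it. The median makes the
factor robust — a single aberrant metabolite cannot move it.

**Autoscaling** centers each log-metabolite and divides by its sample
(n−1) standard deviation, the convention of the major chemometrics
packages, so tests can assert exact values.

**Train/validation hygiene.** All statistics (reference profile, log means
and sds, imputation minima) are fitted on training samples only and applied
frozen to validation samples. Validation data are never refit.

**Block scaling.** For multi-platform fusion, each autoscaled block is
multiplied by 1/sqrt(block width) so every block contributes equal total
variance to the fused matrix; each fused column keeps its platform
provenance in its name.

## Models

**NIPALS PCA** (outlier screen, ≤ 3 components by default). On complete
data the score direction follows power iteration on the sample Gram matrix,
which is where the implementation iterates (O(n²) per step); with missing
cells it falls back to the classical elementwise score/loading regressions.
Convergence is declared when the unit score vector moves by less than 1e-12
between iterations; the iteration cap is generous (200k) because nearly
degenerate eigenvalue pairs slow power iteration, and each step is cheap.
Samples are flagged as outliers when Hotelling
T² = Σ_a t²_a/λ_a exceeds the F-based limit
a(n−1)(n+1)/(n(n−a))·F₁₋α(a, n−a) at the 99% level.

**OPLS-DA.** The class label is coded {0, 1} and centered (no variance
scaling — single binary response). Per orthogonal component: w ∝ Xᵀy
(unit norm), t = Xw, p = Xᵀt/(tᵀt), w_o ∝ p − (wᵀp)w, t_o = Xw_o,
p_o = Xᵀt_o/(t_oᵀt_o), and X is deflated by t_o p_oᵀ. The predictive
component is fitted on the deflated matrix. Consequences used as test
invariants: t ⊥ every t_o, w ⊥ every w_o, and prediction on the training
matrix reproduces the training fit exactly. If no orthogonal variation
overlaps the predictive loading (‖p − (wᵀp)w‖ ≈ 0) the component is simply
not extracted. The number of orthogonal components defaults to 1 (the
structure reported for these serum models); an "auto" rule adds components
while 7-fold Q2Y improves by ≥ 0.01, capped at 5.

**VIP.** With a single predictive component and unit-norm weights,
VIP_j = sqrt(p)·|w_j|, so mean(VIP²) = 1 exactly — asserted on every fit.
Orthogonal components are excluded from VIP, the common OPLS-DA reporting
choice.

**Multi-class stage model.** PLS2-DA: NIPALS PLS2 against the class
indicator matrix (rows summing to one), two predictive components, no
orthogonal filtering. This is documented as an approximation wherever a
labelled O2-PLS-DA might have been used; full two-block O2-PLS is out of
scope.

## Validation machinery

**Q2 from k-fold CV.** Folds are a seeded, class-stratified round-robin
partition — deterministic given the seed, and every training split keeps
both classes (an error suggests fewer folds otherwise). Q2Y = 1 −
PRESS/SS_tot with SS_tot around the full-data label mean.

**Two Q2 flavours.** The *reported* Q2Y refits the final model on its
frozen selected features per fold — the convention of the commercial
software whose outputs these models are usually compared against, and the
value used for the R2Y − Q2Y > 0.2 re-evaluation flag. The *honest* Q2
(cross-model validation) re-runs the data-dependent feature selection —
Welch pre-filter and the VIP cut at the chosen threshold — inside each
fold's training split before refitting. CV-ANOVA is computed from these
honest residuals, because selection bias otherwise masquerades as
predictive power: on effect-free synthetic cohorts, frozen-feature Q2
reaches 0.15–0.48 purely from pre-filter selection, while cross-model Q2
is correctly negative. The VIP threshold value itself is tuned on the full
training set (a mild residual optimism, accepted and documented).

**CV-ANOVA.** F = ((SS_tot − PRESS)/df1)/(PRESS/df2) with df1 = total
components (orthogonal + predictive) and df2 = n − components − 1; p from
the F distribution. These degrees of freedom are an explicit approximation
of the undisclosed accounting in commercial tools.

**Model-level permutation (999 iterations).** Labels are permuted with the
feature set and component structure frozen; each iteration records |Pearson
r| between permuted and original coded labels and the recomputed Q2. A
least-squares line through all permutation points plus the unpermuted point
(r = 1, Q2_model) gives the Q2-intercept at r = 0; the model is valid and
non-random iff the intercept is at or below zero. Empirical p-values use
the add-one estimator (1 + #extreme)/(n + 1), which never returns zero.

**Pre-analysis class permutation (10,000 iterations by default).** The
entire discovery scoring — pre-filter included, VIP refinement optional —
is re-run per permutation, so feature selection sits inside the loop.
Reported are add-one empirical p-values for Q2 (≥ observed) and RMSEP
(≤ observed).

**External validation.** Training/validation sample-id disjointness is
enforced; frozen transforms are applied; the report carries confusion
counts, sensitivity/specificity/accuracy/precision (raw ratios plus
display percentages rounded half away from zero), and AUROC from the
Mann–Whitney statistic with midrank tie handling, with a 95% DeLong CI
truncated to [0, 1].

## VIP threshold selection

For each grid threshold (default 0.5–1.5, step 0.05) the model is refit on
metabolites with VIP ≥ threshold and (R2Y, Q2Y) recorded. Q2Y differences
across thresholds are routinely smaller than the resampling noise of
7-fold CV (±0.02–0.05 at n ≈ 50), so a strict argmax over the grid selects
near-arbitrary, often tiny, models. The selection therefore treats all
thresholds within `q2_tolerance` (default 0.05) of the grid-maximal Q2Y as
equivalent and prefers, among them, the most inclusive model (largest
feature count, hence maximal R2Y), then the smallest R2Y − Q2Y gap, then
the smallest threshold. This realizes the bi-objective "maximize R2Y and
Q2Y with their difference at minimum" rule without letting CV noise drive
feature elimination. A singleton grid (e.g. {1.0}) reproduces the fixed
VIP > 1 rule and is returned unconditionally.

## Synthetic cohorts

The generator emulates a Biocrates-P150-style panel: 163 metabolites in the
kit-convention composition (41 acylcarnitines, 14 amino acids, 38 PC aa,
38 PC ae, 15 lysoPC, 15 SM, 2 other). Concentrations are log-normal on the
log2 scale: per metabolite, a class-typical location (amino acids tens of
µM, lipids 0.1–100 µM — fixture conventions, not cohort claims) plus a
per-sample, per-class latent factor (loading = `within_class_correlation`,
default 0.5, modelling lipid co-regulation) plus independent noise, with
total per-metabolite log2-sd fixed at 1.0. Effect metabolites (default 48,
chosen among detectable metabolites) shift by a signed log2 fold change
drawn from ±U(0.5, 1.5) — which, with unit log2-sd, is the same thing as
0.5–1.5 sd — multiplied by a group factor monotone in disease stage
(adenoma 0.3, stages I/II/III/IVa 0.6/0.8/1.0/1.2; ≈ 1 sd on average over
the training CRC mix). Each sample carries a log-normal dilution factor
(log-sd 0.2) multiplying all metabolites — this is what gives median
fold-change normalization something real to remove — and every cell gets
multiplicative analytical noise calibrated to a QC CoV of 0.10. QC samples
are analytical-noise replicates of the pooled geometric mean. Seventeen
designated metabolites are censored below their 60% quantile so the LOD
gate retains 146 of 163; ordinary metabolites are sporadically censored at
the 2% quantile to exercise imputation. Group sizes mirror the study
cohort: 21/20 controls (train/validation), 31 adenomas, and CRC stages
I/II/III/IVa at 5/5/5/17 train and 3/3/3/19 validation — 53 training and
48 validation samples for the CRC contrast.

What the generator does *not* emulate: batch/plate drift, heteroscedastic
(concentration-dependent) analytical error, non-Gaussian biological
distributions, covariate structure (age/sex effects on metabolites), and
realistic correlation beyond one factor per class. Passing recovery tests
therefore show that the pipeline's logic is sound under its stated noise
model, not that equivalent performance is guaranteed on real cohorts.

**Dilution-factor recovery bound.** With dilution log-sd 0.2, biological
log-sd ≈ 0.69 (1.0 in log2), and one shared factor per class at loading
0.5, the median-of-146-ratios estimator has irreducible noise of roughly
0.07 (independent part) plus ~0.14 (shared class factors) in log units, so
the correlation between estimated and true dilution factors plateaus
around 0.7–0.8 (and below ~0.95 even with no class correlation). The
recovery test asserts rho ≥ 0.6 plus exact idempotence under a frozen
reference; near-perfect recovery would require biologically implausible
settings (tiny biological variance relative to dilution).

## Numerical choices and degenerate inputs

- NIPALS tolerances as above; non-convergence raises with diagnostics.
- OPLS-DA requires ≥ 2 samples per class and n_orth < rank(X); an
  orthogonal component with vanishing weight norm (< 1e-12) ends extraction
  early rather than fabricating a direction.
- Zero-variance metabolites are rejected by name at autoscale fit time.
- Percentages round half away from zero (so 92.857 → 93, 96.296 → 96).
- Kruskal–Wallis with all-equal observations returns H = 0, p = 1; the
  chi-square approximation is used throughout (an exhaustive permutation
  oracle covers tiny inputs in the tests).
- Hierarchical clustering uses 1 − Spearman rho with complete linkage;
  constant items are rejected by name since rho is undefined for them.
- Empirical permutation p-values use the add-one estimator.
- All randomness (fold assignment, permutations, synthetic data) flows
  from explicit integer seeds; the same seed yields byte-identical JSON
  artifacts.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the whole workflow at the
study's own scale (53 training / 48 validation samples, 163 → 146
metabolites). Replicated stochastic checks use 20 cohort replicates for
recovery/AUROC, 50 effect-free cohorts for the false-validation rate (199
permutation iterations per null cohort, 999 for the informative cohort),
and 10,000 null features for Welch type-I calibration. The 10,000-iteration
pre-analysis permutation default is exercised at reduced iteration counts
in the checks; the count is a plain parameter.

## Known limitations

- CV-ANOVA degrees of freedom are approximate (see above); p-values should
  be read as indicative, as in the software tradition it mirrors.
- The stage model is PLS2-DA, not O2-PLS-DA; orthogonal filtering is not
  applied in the multi-class case.
- Fusion fits a single OPLS-DA on block-scaled concatenated data; a full
  two-block O2-PLS decomposition (with block-specific orthogonal spaces) is
  out of scope.
- The Q2-intercept criterion does not detect feature-selection overfitting
  when selection happened outside the permutation loop — that is precisely
  why CV-ANOVA uses cross-model validation and why the pre-analysis
  permutation re-selects per iteration.
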
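# Methods

This note documents the models, estimators and design choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## Dose-response fitting and ICx interpolation

Single-agent viability is normalized to vehicle/blank controls and fitted
with the four-parameter log-logistic `v(d) = bottom + (top − bottom)/(1 +
(d/IC50)^h)`. By default the curve is constrained to top = 1, bottom = 0,
because the screen's viability is normalized to vehicle; the unconstrained
fit is available for partial responders. Fitting uses nonlinear least
squares with 8 Latin-hypercube starts over (h ∈ [0.3, 5], IC50 within the
observed dose range), both on log scale; the lowest-RSS solution wins, ties
broken toward the shallowest slope. Curves whose observed viability spans
less than 0.1 are declared non-converged (flat; ICx undefined), and ICx
queries on them refuse. ICx inversion is closed-form,
`d = IC50·((top − v*)/(v* − bottom))^(1/h)` with v* = 1 − x/100, and raises
with the achievable inhibition span when x is outside (1 − top, 1 − bottom).
IC0 is by convention dose 0 and is handled by the design layer, never
passed through the log transform.

## OACD construction

The screen design concatenates a 2^(12−5) two-level fractional factorial
(128 runs, coded −1/+1 = absent/IC30) with the three-level orthogonal
array OA(27, 3¹³) restricted to its first 12 columns (27 runs, coded
−1/0/+1 = absent/IC15/IC30), giving 155 runs. The OA is constructed from
GF(3) linear combinations of three base columns in a pinned order; any
column carries each level 9 times and any column pair each level
combination exactly 3 times (strength 2).

The generator words for the two-level block are pinned to
8 = 2·3·4·5, 9 = 3·4·7, 10 = 1·2·4·7, 11 = 1·2·4·5·6, 12 = 2·6·7.
This set is resolution IV (no main effect aliased with a two-factor
interaction) and was selected, by enumeration over candidate generator
sets, so that the *combined* 155-run design has a full-rank 91-column
second-order model matrix. These two properties are in tension: every
resolution-IV 2^(12−5) design has some length-4 defining words, each of
which aliases three pairs of two-factor interactions inside the two-level
block, and the 27 extra runs can only break a limited number of those
aliases. Textbook generator sets built from 3-letter words alone leave the
combined rank at ≤ 88; the pinned set has only two length-4 words and
reaches rank 91. The run order and plate layout of any particular
laboratory screen are not reproducible and not attempted; run count,
balance, orthogonality and estimability are the reproduced properties.

## Quadratic surface model and pair ranking

The model matrix columns are pinned as [1, xᵢ, xᵢ², xᵢxⱼ (i<j
lexicographic)]. Fitting is plain OLS — no shrinkage; the OACD guarantees
estimability and rank-deficient inputs are refused rather than silently
regularized. Fitting replicate-averaged viability is identical to fitting
stacked replicates (OLS equivalence), asserted in the tests.

Two-drug combinations are scored by predicted viability with the two drugs
at each of the four (IC15/IC30)² level assignments and **all other drugs at
level −1 (absent)**; a pair's headline score is its minimum over the four
assignments, and pairs are ranked ascending (lower viability = stronger
combination). A consequence of the symmetric ±1 coding is that the
interaction coefficient βᵢⱼ contributes identically (+βᵢⱼ) at the
both-absent and both-at-IC30 corners, so a negative interaction manifests
as sub-additivity against the single-drug edges (visible in the response
surface) but does not by itself separate a pair from the rest of the
ranking; the synthetic truth therefore encodes its planted top pair with
both the strongest single-agent effects and the planted interaction (see
below).

## Synergy statistics

The median-effect fit regresses log₁₀(fa/(1−fa)) on log₁₀(dose), excluding
points with fa outside (10⁻⁴, 1 − 10⁻⁴) where the logit is undefined or
plate noise dominates. The combination index uses the two-term mutually
exclusive form (the standard recommendation, and the form matching
two-term Fa-CI plots); the sham self-combination identity CI ≡ 1 holds to
1e−6 and is tested as a property over (Dm, m). The Bliss score averages
observed-minus-expected inhibition over combination cells only — margins
have zero excess by definition and would dilute the score — and is
classified synergistic above +10, antagonistic below −10. Matrices are
scored raw; no smoothing of the dose-response margins is applied, so
scores on noisy matrices can differ from tools that internally re-fit the
margins before computing the expectation.

## Clonogenic analysis

PE = colonies/plated, SF = PE_irradiated/PE_control, and the LQ model
SF(D) = exp(−(β₁D + β₂D²)) is fitted with β₁, β₂ ≥ 0. Two fitters are
provided. `fit_lq` is unweighted nonlinear least squares on the SF scale
(the conventional survival-curve fit), with the linearized −ln SF
regression as initializer and independent cross-check. `fit_lq_counts` is
a binomial-likelihood fit directly on colony counts with the unirradiated
plating efficiency as a jointly estimated nuisance parameter; it weights
each dose by its true counting noise and is markedly more efficient,
especially for β₂. Even so, with a 0/1/2/4 Gy ladder and triplicate
500-cell dishes the Fisher information limits β₂ = 0.03 Gy⁻² to a median
relative error around 28% (β₁ around 10%); this is a property of the
sampling design, not the estimator, and the package reports both errors
honestly.

The radiosensitization ratio is operationalized as SF_control(4 Gy) /
SF_treated(4 Gy) — the fold-reduction in survival attributable to the drug
at the reference dose; the mean-inactivation-dose ratio is available as an
alternative summary. Tumor volume uses the ellipsoid formula
V = π/6·L·B·H and the growth rate is the endpoint difference divided by
elapsed days.

## Differential expression and the selection cascade

The DE stage is deliberately a *simplified* negative-binomial Wald test,
not a re-implementation of a full NB GLM framework: counts are normalized
by median-of-ratios size factors; a common dispersion is estimated as the
5–95% trimmed mean of per-gene pooled moment estimates (genes with
normalized mean > 5); the per-gene statistic is the log-ratio of group
means (pseudocount 0.5) over its delta-method standard error
√((1/μ̂₁ + α)/n₁ + (1/μ̂₂ + α)/n₂), referred to a normal. Contrasts are
computed per cell line and combined across lines as strata (mean log2FC,
Stouffer z), which adjusts for the cell-line factor. Calibration was
checked on null NB data (raw p < 0.05 rate within [0.03, 0.07] at 5000
genes) and power on planted |log2FC| = 2 effects (> 90%). Externally
produced DE tables (gene, log2fc, padj) can be supplied and bypass this
stage entirely.

Thresholding keeps |log2FC| > 0.5 AND BH-adjusted p < 0.1, both strict.
Interaction analysis intersects the two thresholded contrasts and keeps
genes with opposite fold-change directions (dysregulated in RR, reversed
by knockdown). Refinement computes, per cell line, δ_WT =
mean(WT-siHDAC6)/mean(WT-control) and δ_RR likewise on size-factor-
normalized means with pseudocount 1, and retains genes with
sign·log₂(δ_RR/δ_WT) > 1, where the sign aligns the ratio to the gene's
knockdown-response direction so "> 1" always means a stronger response in
the RR cells (an absolute-value variant is available). The consensus is
the intersection across cell lines, with per-line retention percentages
reported to one decimal. Each stage's output is a subset of its input and
the per-gene trace records the full implication chain.

Because the RR-vs-WT and knockdown contrasts share the RR-control group, a
single outlying replicate in that group can mimic the opposite-direction
pattern in both contrasts; such genes are the dominant source of the small
number of false positives observed in recovery simulations (median 1 per
20,000 genes under default conditions).

## Survival analysis

Per-gene screening median-dichotomizes the cohort (ties to "low") and fits
a Cox proportional-hazards model on the binary indicator with Efron tie
handling, reporting the HR in a declared orientation (Higher/Lower or
Lower/Higher expression as numerator). The directional filter keeps genes
whose significant (p < 0.05) hazard orientation matches their RR
dysregulation direction. The combined signature is the equal-weight mean
of per-gene z-scores of log2(expression + 1) — the minimal-assumption
reading of a "combined expression score" — median-dichotomized on the
evaluation cohort. Kaplan–Meier curves, the two-sided log-rank test and
the low-vs-high Cox HR summarize group separation.

## Synthetic data: what it emulates and what it does not

All generators are deterministic given their seed and emit machine-
readable truth objects.

* **Screen truth**: a second-order surface over 12 coded drugs. Linear
  coefficients are drawn in [−0.030, −0.015] per coded unit — mild enough
  that all 155 noiseless predictions stay inside the plate's [0, 1.2]
  viability range (so the clip never distorts noiseless data) — with the
  planted pair at −0.085 each plus an interaction of 0.15 (3× the plate
  noise σ = 0.05), sign negative for synergy. The margin was sized by a
  power analysis of fitted pair-score differences (SD ≈ 0.05 under
  duplicate σ = 0.05 noise against ~65 competitor pairs) so the planted
  pair is the truth surface's unambiguous #1 and is recovered as rank 1 in
  ≈98% of noisy screens. Viability noise is additive Gaussian on the
  normalized scale, clipped to [0, 1.2]; technical duplicates by default.
* **Dose-response plates**: log-logistic curves over the 0.0001–100 µM
  ladder (10 log steps), hill ∈ [0.7, 2.5], IC50 ∈ [0.01, 10] µM,
  quadruplicate, with an emulated luminescence scale.
* **Bliss matrices**: 5×5 with margins; combination cells follow the Bliss
  expectation exactly (null) or plus a constant planted excess.
* **Clonogenic counts**: colonies ~ Binomial(plated, PE₀·SF_LQ(D)) at
  0/1/2/4 Gy, default β₁ = 0.3 Gy⁻¹, β₂ = 0.03 Gy⁻², PE₀ = 0.5, triplicate
  500-cell dishes.
* **Counts**: negative binomial over 2 cell lines × 2 phenotypes × 2
  knockdowns × 3 replicates (24 samples). Gene-wise dispersions are
  log-normal around 0.05 (σ = 0.3); library-size factors log-normal(0,
  0.2); baselines log-normal around 100 with planted genes drawn from
  [50, 1000] (selected genes are detectable in practice). Planted
  structure: 24 consensus genes (4 up / 20 down, identical in both lines,
  fully reversed by knockdown, |log2FC| ∈ [1.5, 2.5]), line-specific
  responsive genes (76/30), 200 knockdown-inert RR genes and 50
  same-direction responders, so every cascade stage has something to
  reject.
* **Cohorts**: exponential event times with administrative uniform
  censoring (horizon 1.5 × the baseline mean, giving ≈55% events at
  n = 261). In the default dichotomous mode the excess hazard exp(β)
  applies to the below-median signature group, so the *true dichotomized
  HR* is exactly exp(β) and CI coverage is directly interpretable; a
  continuous per-gene-coefficient mode is also available.

Not emulated: batch effects, plate spatial effects, read-level sequencing
artifacts, gene–gene correlation, non-proportional hazards, and cohort
covariates. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative models, not robustness to
real-data pathologies.

## Numerical choices and degenerate inputs

Key tie-breaks and guards: dose-response multi-start ties go to the
smallest hill; median splits send ties to "low"; Bliss inhibitions outside
[0, 100] are clipped with a warning; fa is clamped at 10⁻⁴ before the
logit; negative normalized viability clips to 0 with a warning; SF > 1
passes through with a warning; all-equal viability, all-equal expression,
zero-event groups, missing factorial groups and rank-deficient designs
raise informative errors. All thresholds (0.5/0.1/1.0 selection, ±10
Bliss, 0.05 directional alpha, 4 Gy reference dose) live in
`PipelineConfig`, and every pipeline run writes its resolved configuration,
log, version stamp and artifact checksums.

## Problem sizes

Recovery simulations use the study-scale conditions throughout: the full
155-run screen at 100 seeds for ranking recovery, 20,000 genes × 24
samples at 20 seeds for the cascade, n = 261 cohorts at 200 seeds for
survival calibration, and 100 seeds for clonogenic refits — sizes chosen
so the complete suite runs on a laptop-class single CPU in well under a
minute per stage.
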
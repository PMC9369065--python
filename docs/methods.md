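# Methods

## Problem setting

A chilling timecourse with a small replicated design (default 4 timepoints
× 3 replicates = 12 RNA-Seq libraries) yields a gene × sample count matrix
and an FPKM matrix.  The analysis asks three questions: which genes
respond to chilling at every timepoint (the chilling-responsive gene set,
CRGs); how do those genes organize into hormone-signaling,
transcription-factor, and antioxidant blocks; and how strongly does
hormone-pathway activity act on the antioxidant system directly versus
through the ICE1/CBF/bZIP transcription-factor layer.  The last question
is answered with PLS path modeling, the first with a negative-binomial
Wald screen.

## Differential-expression screen

**Normalization.** Median-of-ratios size factors: for each sample s,
factor_s = median over genes g (restricted to genes with a positive
geometric mean across samples) of count_gs / geomean_g.  All testing is on
counts divided by these factors.

**Dispersion.** The NB variance is parameterized as var = μ + αμ² (α = 0
is Poisson; the same convention the count simulator uses).  Per gene, the
raw method-of-moments estimate (s² − x̄)/x̄² is computed within every
timepoint group with ≥ 2 replicates, df-weighted across groups, and
floored at 10⁻⁸.  Pooling over the whole design rather than the two
contrasted groups is deliberate: it doubles the degrees of freedom in the
4 × 3 layout (8 vs 4), and at triplicate group sizes that difference
decides whether the normal-reference Wald test is usable at all —
measured over several simulation seeds, two-group pooling gives a null
p ≤ 0.05 fraction of ≈ 0.11, whole-design pooling ≈ 0.08–0.09.  It also
matches how count-based DE tools actually operate: dispersions are fitted
once from all samples and shared across contrasts.

**Test.** Per gene, log2fc = log2((x̄_t + c)/(x̄_c + c)) with pseudocount
c = 0.5 on normalized counts; by the delta method the Wald SE is
sqrt(v_t/(n_t(x̄_t + c)²) + v_c/(n_c(x̄_c + c)²))/ln 2 with v_g = x̄_g + αx̄_g²;
two-sided p from N(0, 1); BH step-up FDR within each contrast separately.
Genes with all-zero counts are dropped before testing (logged).  A
zero-SE gene is assigned p = 1 when its fold-change is also zero and p = 0
otherwise.  No dispersion shrinkage across genes, no outlier refitting —
the screen depends only on the two thresholds, and every number is
reproducible by hand from the formulas above.

**Screen and CRGs.** A gene passes one contrast iff FDR ≤ 0.01 and
|log2fc| ≥ 1 (fold-change ≥ 2), both boundaries inclusive; the CRG set is
the intersection across all treatment-vs-control contrasts, with all Venn
region sizes reported.

## Gene blocks, enrichment, Z-scoring

Blocks come from a (gene, label) annotation table over the controlled
vocabulary {ABA, IAA, CTK, ETH, BR, GA, JA, SA, SL, ICE1, CBF, bZIP, AO};
unknown labels are kept as user-defined terms with a warning.  A gene may
carry several labels and then sits in several blocks; unlabeled CRGs are
listed as unassigned, so blocks ∪ unassigned always covers the CRG set.
Over-representation uses the upper-tail hypergeometric probability of the
observed overlap (empty label sets get p = 1), BH-adjusted across labels.
Z-scoring is per gene row, (x − mean)/sd with sample sd (n − 1);
constant rows map to zero and are logged.

## PLS path model

**Model.** Latents are measured reflectively (Mode A): each indicator
gene is modeled as loading × latent + noise, the natural reading of
transcripts reflecting an unobserved pathway activity, and the one under
which "factor loadings" are meaningful.  Structural edges form a DAG; the
default topology per hormone H is H → ICE1, H → CBF, H → bZIP (first-order
pathways), ICE1/CBF/bZIP → AO (second-order), and the direct H → AO edge.
The three TF families are separate latents by default (configurable): it
keeps each family's mediation route identifiable in the effect
decomposition.

**Estimation (Lohmöller iteration).** Indicator columns are standardized
(population n denominator — path coefficients and loadings are invariant
to this; it is pinned so latent scores are bit-stable).  Outer weights
start at 1 and are kept unit-norm per block.  Each round: (outer) latent
score = standardized weighted sum of its indicators; (inner, path scheme)
the weight of a predecessor is its coefficient in the multiple OLS of the
latent's score on all its predecessors, the weight of a successor is the
score correlation (centroid: sign of correlation; factorial: correlation);
the inner proxy is the standardized weighted neighbor sum; (outer update,
Mode A) each weight becomes corr(indicator, own proxy).  Convergence is
max |Δ weight| < 10⁻⁷ (max 300 iterations; non-convergence warns and
returns the last iterate, flagged).  After convergence each latent is
oriented so its loading sum is positive (a Σλ = 0 tie keeps the current
sign); loadings are indicator–score correlations; path coefficients and
R² come from per-endogenous-latent OLS on predecessor scores.  With
single-indicator latents the procedure collapses to Pearson correlation
(one predecessor) or standardized multiple OLS — the test suite holds
both equivalences to 10⁻¹⁰.

PLS needs only correlations, so n below the indicator count is allowed —
it is the regime of a real 12-library study feeding blocks of up to ~60
genes — but triggers a prominent low-sample warning; estimates there are
honest but unstable.

**Validity metrics.** AVE = mean λ² per latent (≥ 0.5, inclusive, is the
pass bar in `validate_model`); composite reliability
(Σλ)²/((Σλ)² + Σ(1 − λ²)).

**Effects.** With coefficient matrix B, total = Σ_{k≥1} B^k (exact for a
DAG, nilpotent); indirect = total − direct.  For the default topology the
indirect hormone → AO effect is a₁b₁ + a₂b₂ + a₃b₃ over the three
mediator routes.

**Bootstrap.** B resamples of sample rows with replacement (default 5000),
each refit in full; non-convergent or degenerate resamples are dropped and
counted.  Sign policy "individual": every resampled outer weight and
loading is flipped individually to the sign of the original estimate;
each construct's orientation is then set by the majority sign agreement
of its loadings, and each path coefficient is multiplied by the product
of its two constructs' orientations before aggregation.  ("construct"
flips whole blocks by the majority rule only; "none" aggregates raw.)
SE is the sd of aligned estimates; t = original/SE with a two-sided
normal-reference p (percentile CIs are reported alongside, since the
reference distribution is a convention, not a derivation).

**Input transform.** The PLS stage consumes row-Z-scored expression by
default.  Since columns are standardized inside the fit anyway, any
per-gene affine transform of the input leaves all estimates unchanged
(tested); the default is pinned only so written latent scores are
reproducible.

## qPCR validation

ΔCt = Ct_target − Ct_reference per sample (technical replicates averaged
on the Ct scale first, the convention of the 2^−ΔΔCt method); ΔΔCt is
relative to a calibrator sample, which maps to exactly 1.  Concordance
regresses qPCR log2 fold-changes (y) on RNA-Seq ones (x) by OLS, with
Pearson r and a t-based two-sided p (n − 2 df).

## Synthetic-data generator

The generator emulates the study design, not its unpublished data: a
4 × 3 count matrix plus a continuous indicator matrix with latent
structure.

*Latents.* Exogenous latents are i.i.d. N(0, 1).  Each endogenous latent
is Σ β·parent + residual, with the residual variance solved from the
implied covariance so every latent has population variance exactly 1 —
configured βs are then directly the standardized coefficients PLS
estimates, and corr(A, B) → β for a single-parent edge (verified at
n = 10⁵ within ±0.01).  A configuration whose explained variance exceeds
1 is inadmissible and raises; `variance_policy="rescale"` instead shrinks
that latent's incoming coefficients by 1/√explained (residual 0) and
reports the realized coefficients as the truth.

*Indicators.* x = λ·latent + N(0, σ²) per sample; by default σ =
√(1 − λ²), giving unit-variance indicators, so corr of two same-block
indicators is λ₁λ₂.  The continuous matrix is on a log-expression scale
and is what the PLS stage consumes.

*Counts.* Gene counts are NB(μ, α) with var = μ + αμ².  A fraction
`de_fraction` of genes (sampled per gene) has mean μ·2^de_log2fc at every
non-control timepoint.  Defaults — baseline mean 100, dispersion 0.05,
de_fraction 0.1, de_log2fc 2, 2000 genes — are stated choices for a
realistic moderately-expressed, moderately-overdispersed transcriptome
slice, not values inferred from any dataset.

*What it does not emulate.* Library-size variation beyond median-of-ratios
scale, mean-dependent dispersion trends, gene–gene correlation outside the
configured blocks, time-profile shapes (the DE effect is a step, not a
trajectory), and any sequence-level process.  Passing tests therefore
show the estimators recover the generative model they assume; robustness
to realistic violations (dispersion trends, outliers) is untested by
design.

## Numerical choices and degenerate inputs

- Dispersion floor 10⁻⁸; pseudocount 0.5; BH ties share the step-up
  minimum.
- PLS tolerance 10⁻⁷ on unit-norm weights, all-ones initialization,
  max 300 iterations.
- Latent sign ties (Σλ = 0) keep the current orientation.
- Zero-SE bootstrap parameters: t = 0 if the original estimate is 0,
  ±∞ (p = 0) otherwise.
- Constant indicator columns are an error in the original fit and a
  dropped-resample condition inside the bootstrap.
- All numeric TSV/JSON outputs use a pinned float format ("%.10g") so
  identical seeds give byte-identical files.

## Simulation sizes used in the checks

The method-level checks run at sizes chosen to make their statistical
assertions sharp while staying desk-scale: oracle equivalences at
n = 10–80; parameter recovery on the 5-latent mediation DAG at n = 500,
loadings 0.9, 20 seeds with B = 1000 bootstrap resamples; bootstrap SE
against the analytic correlation SE at n = 200, B = 2000; screen
calibration and power at 2000 genes; Monte-Carlo generator calibration at
n = 10⁵.  The end-to-end determinism check runs the full pipeline on the
default 2000-gene fixture with B = 500.

## Known limitations

- The DE screen's Wald p-values are approximate at triplicate group
  sizes (null p ≤ 0.05 fraction ≈ 0.08, not 0.05); the screen additionally
  gates on fold-change, which dominates its behavior in practice.
- PLS path estimates are attenuated by measurement error at finite block
  sizes (consistency-at-large); with loadings 0.9 and 3–10 indicators the
  bias is ≈ 3–5% of the coefficient, visible in the recovery tests.
- The bootstrap sign-change conventions follow SmartPLS 2.0's documented
  behavior as closely as its manual specifies; where the manual is silent
  (construct re-orientation for path aggregation), the majority-of-aligned-
  loadings rule is used and pinned.
- Formative (Mode B) measurement, blindfolding/Q², and higher-order
  constructs are out of scope.
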
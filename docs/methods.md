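# Methods

## Study design and data model

The package analyses cohorts in which every patient contributes one benign
(NF) and one malignant (MPNST) sample with a shared genetic background. All
expression analyses operate on the per-patient subtraction

    Δg(p) = log2(TPM_g(MPNST_p) + 1) − log2(TPM_g(NF_p) + 1),

so patient-level confounding (genotype, differentiation lineage) cancels to
first order and only transformation-associated changes remain. The +1 offset
maps TPM 0 to exactly 0 and keeps the transform monotone; it is the only
normalisation applied — TPM is assumed already within-sample normalised.

Telomere content is carried per sample in "intratelomeric reads per million
GC-matched reads" units; it is a relative proxy for telomere length, and no
base-pair conversion is attempted because none is defined for this statistic.
Telomere-dependent analyses use only patients with content for both samples
(listwise deletion) and always report the n used; the data model explicitly
tolerates missing pairs (the motivating design has 19 of 20 complete pairs).

## Paired DEG selection

Per gene: a two-sided paired t-test on the Δ values (t = mean/(sd/√n),
df = n−1) and a fold-change gate. "Average fold change ≥ 2" is interpreted on
the log scale — |mean Δ| ≥ 1, i.e. a geometric-mean fold change — because the
analysis is defined on log2(TPM+1) and arithmetic-mean ratios are unstable
when benign-state TPM is near zero. An arithmetic mode (ratio of mean
reconstructed TPM) is available (`fc_mode="arithmetic"`) for comparison.
The fold-change gate is inclusive (≥), the p gate strict (< 0.001), and no
multiplicity correction is applied at this stage; the screen that consumes
DEGs carries the FDR control. Degenerate genes (zero Δ variance) are flagged:
p is reported as a 0-limit when the mean is nonzero and as undefined when it
is zero, never silently as 0 or 1.

## Composite cascade screen

For each ordered pair (A, B) over the source × target sets:

* `lr_delta`: OLS of ΔB on ΔA — does the change in A predict the change in B?
* `lr_target`: OLS of the malignant-sample B level on ΔA — is the end state of
  B, not merely its change, driven by ΔA?
* `glm_telomere`: Gaussian-identity GLM of malignant-sample telomere content
  on ΔA and ΔB — is the pair coupled to the telomere-maintenance axis?

All three p-value families are pooled into a single Benjamini–Hochberg
step-up adjustment at FDR 0.1 (a per-family mode exists but is off by
default). A hit requires all three B-H rejections plus positive `lr_delta`
and `lr_target` slopes; the GLM coefficient's sign is deliberately
unconstrained, since telomere coupling can be negative for a genuine
transcriptional activation. Pairs that cannot be fitted (constant source
delta, fewer than 4 complete telomere patients, rank-deficient design) are
reported as skipped rather than dropped.

The GLM statistic is configurable because the choice is genuinely open:

* `interaction` (default): coefficient of ΔA·ΔB in 1 + ΔA + ΔB + ΔA·ΔB.
* `main_effect_A`: coefficient of ΔA in 1 + ΔA + ΔB.
* `joint`: F-test that ΔA and ΔB jointly predict telomere content (model
  1 + ΔA + ΔB vs intercept-only), reported with the ΔA coefficient.

For planted-cascade recovery (and the pipeline preset) we use `joint`: when
the underlying telomere model is *linear* in the deltas and B is an almost
deterministic linear function of A, the interaction regressor ΔA·ΔB is nearly
collinear with the main effects and its coefficient estimates ~0, while the
individual main effects are mutually masked; the joint F-test is the statistic
that remains well-posed along a tight cascade.

Exact-fit p-values (zero residual variance) are floored at machine epsilon
before B-H; this avoids NaNs and cannot change any rejection decision.
Residual sums of squares at numerical-noise level (relative 1e-10) are
treated as exact fits: coefficients indistinguishable from zero get p = 1,
others a 0-limit p = 0, so constant outcomes do not produce arbitrary
t-ratios of rounding errors.

Shipped screen presets mirror the motivating workflow: 22 transformation DEGs
× 9 PAX genes (198 pairs, 594 pooled p-values); {PAX7, PAX5} × 100
telomere-maintenance (TMM) genes (200 pairs); and 4 DNA-damage markers
(H2AFX, PARP1, TP53, RB1) × TMM genes, where the pair-enumeration rule is a
parameter: excluding only self-pairs gives 4 × 99 = 396 pairs (the published
total for this stage, and 596 pairs / 1788 pooled p-values with the PAX
stage), excluding all four markers from the target side gives 4 × 96 = 384.
The 100-gene TMM table (four functional categories) ships as an editable TSV;
it is a curation, not a ground truth.

## Telomere association

Simple mode fits one univariate OLS per gene; multiple mode fits one joint
OLS with all genes (plus intercept) and reports partial coefficients with
t-based 95% CIs. With ~19 patients and 5 covariates OLS is deliberate — no
regularisation, matching the small-cohort analysis style this implements.
Rank-deficient designs are rejected with a condition-number diagnostic.

## Dichotomized survival

Groups are Δfactor > 0 ("increased") vs Δfactor ≤ 0 — zero change counts as
not increased. Cox proportional hazards with a single binary covariate is fit
by statsmodels PHReg; Breslow tie handling is the default (the analysis style
this reproduces used SPSS, whose default is Breslow) with Efron by flag.
Wald CIs and p-values are reported. If every event falls in one group the
partial likelihood is monotone: the result is flagged
`monotone_likelihood` and the CI reported as unbounded instead of a
pseudo-converged interval. MFS analyses are restricted to
metastasis-evaluable patients. Kaplan–Meier curves come from lifelines;
high-grade association uses logistic regression of FNCLCC grade 3 vs {1, 2}
(configurable), with complete separation detected from the 2×2 margins and
Wald statistics suppressed when the MLE does not exist.

## Telomere content from reads

A read is intratelomeric when it carries at least t non-overlapping TTAGGG
repeats, counted on whichever strand (forward motif or its reverse complement
CCCTAA) yields more; repeats need not be consecutive. The default threshold is
length-proportional: t = floor(read length × 6/100), at least 1 — a rule in
the spirit of telomere-read extractors whose exact defaults are
length-dependent. GC fraction is (G+C)/(A+C+G+T) with N bases excluded
entirely; all-N reads have undefined GC and never enter the denominator. The
GC window [0.48, 0.52] is inclusive at both bounds ("between 48% and 52%"
read inclusively; a pure-repeat read has GC exactly 0.50). Content is
undefined (an error, not 0) when no read falls in the window.

Deliberate simplifications relative to full alignment-based telomere callers:
no alignment-coordinate or mapping-quality stratification into telomeric
regions (every repeat-passing read counts as intratelomeric), no variant
repeats (TGAGGG, TCAGGG, …), no per-chromosome assignment, no singleton
correction, no tumor/control log-ratio mode. SAM/BAM input is supported but
only read sequences are used.

## Synthetic cohort generator

The generator emulates exactly the structure the analyses assume:

* NF log2(TPM+1) ~ Normal(mu_g, sigma_g) per gene (default mu ~ U(3, 8),
  sigma 1.0 — typical bulk-expression spread on the log2 scale);
* MPNST = NF + d·1[g ∈ DEG] + Normal(0, pair_sd); the within-pair noise
  pair_sd defaults to 0.8 (1.0 in the study-shaped fixture) and is the sole
  source of Δ variance for unplanted genes;
* cascade edges (processed in order, so chains propagate):
  ΔB = beta·ΔA + Normal(0, sd), with the malignant B value rebuilt as
  NF_B + ΔB so that both screen regressions are satisfiable;
* telomere: NF = alpha0 + ε, MPNST = alpha0 + offset + Σ alpha_g·Δg + ε,
  ε ~ Normal(0, noise_sd). The offset models transformation-wide telomere
  attrition unrelated to the planted cascade; in the study-shaped fixture it
  is −273 content units, the scale of the observed mean NF→MPNST decline in
  the motivating cohort, which also keeps the Δtelomere > 0 split
  non-degenerate for the survival stage;
* survival: exponential event times with hazard λ·exp(logHR·1[Δfactor > 0])
  per endpoint (OS baseline 0.02/month, MFS 0.025/month, logHR ln 3.8 in the
  fixture), censored at min(60-month administrative horizon, U(0, 120) dropout).

Log-expression is clipped at 0 before emission (TPM = 2^log − 1 is never
negative), and every downstream quantity — cascade, telomere, ground truth —
is derived from the clipped values, so a round trip through the TSV writers
and readers is numerically exact. One integer seed drives a single generator
stream; identical config + seed reproduces the cohort bit for bit.

The study-shaped fixture: 20 patients, 131 genes (22 planted DEGs at ±2 log2
units, PAX1–9, 100 TMM genes), cascade NELL2→PAX7 (beta 0.335, the reported
slope for that edge) and PAX7→RAD52 (beta 0.8), telomere coefficient +400 per
ΔRAD52 unit with noise sd 50, one missing telomere pair, 14 of 20 patients
metastasis-evaluable. The cascade targets carry low benign-state baselines
(PAX7 mu 0.5, sigma 0.2; RAD52 mu 3.0, sigma 0.15): developmental factors
like PAX7 are near-silent in benign tissue, and this is also what makes the
malignant-level regression informative at n = 20. Effect sizes are chosen for
detectability at this cohort size, not estimated from data; the telomere
noise (sd 50) is far below realistic content dispersion (~420 in the
motivating cohort) because at n = 19 a paper-scale noise level leaves the
composite screen underpowered by design.

What passing tests on this generator do **not** show: robustness to
count-level noise (simulation is at the log-TPM level, not reads), to
library-size or batch effects, to non-Gaussian expression, to informative
censoring, or to confounded pairings. The null fixture shares the shape with
no planted effects and realistic telomere noise (sd 420) and anchors the
false-positive-control checks.

## Numerical and testing choices

* OLS inference in the screen's inner loop is scipy's linregress plus t
  quantiles (tens of thousands of fits in the Monte-Carlo checks);
  statsmodels OLS serves as the independent oracle in tests, and B-H wraps
  statsmodels' multipletests with a literal step-up enumeration as oracle.
* The Cox oracle test uses a 4-record sample with alternating group labels;
  with both early events in one group the Breslow partial likelihood is
  monotone in the coefficient and has no interior maximizer to compare
  against.
* Monte-Carlo scales: 100 seeds for slope/DEG recovery at n = 20, one n = 500
  cohort for hazard-ratio recovery (tolerance 15%), 200 null replicates for
  false-positive control. These sizes give stable pass/fail margins at
  one-CPU runtimes of a couple of minutes.
* Determinism: analyses draw no random numbers; pipeline reruns on the same
  inputs are byte-identical. All simulation randomness flows through
  numpy's default_rng seeded from one integer.

## Known limitations

* The screen is correlational; "activation" is a labelled statistical
  pattern, not causal inference or mediation analysis.
* Pooling three heterogeneous test families into one B-H vector means a
  strongly telomere-coupled gene inflates the rejection threshold for the
  regression families; along a planted cascade this occasionally promotes a
  neighbouring spurious edge at n = 20. The per-family pooling mode trades
  this for stricter family-wise behaviour.
* With ~20 patients the multiple-regression and Cox estimates are
  small-sample; Wald intervals are reported without small-sample corrections,
  matching the analysis style this package reproduces.
* The telomere-content estimator is intentionally reduced (see above) and its
  absolute scale is not comparable to full TelomereHunter output; within-run
  contrasts (NF vs MPNST) are the supported use.
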
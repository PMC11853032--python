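# telocascade

Analysis toolkit for **paired benign→malignant tumor cohorts**, built around the
"malignant-transformation subtraction" design: each patient with type 1
neurofibromatosis (NF1) contributes a benign neurofibroma (NF) and the malignant
peripheral nerve sheath tumor (MPNST) that arose from it, so the per-patient
difference of expression profiles isolates transformation-related changes from
the shared genetic background.

Who it is for: computational biologists analysing small paired tumor/precursor
cohorts (bulk RNA expression + WGS-derived telomere content + clinical
follow-up) who want the whole chain — differential expression, cascade
screening, telomere association, survival — as one tested, scriptable pipeline.

## The method

Working on Δg(p) = log2(TPM+1) of the malignant sample minus the benign sample
for gene *g* in patient *p*:

1. **Paired DEG selection** — gene *g* is differentially expressed when the
   geometric-mean fold change satisfies |mean_p Δg(p)| ≥ log2(2) and the paired
   t-test on Δg has p < 0.001 (no multiplicity correction at this stage).
2. **Composite transcriptional-cascade screen** — for every ordered gene pair
   (A, B), three tests: OLS of ΔB on ΔA; OLS of the malignant-sample B level on
   ΔA; and a Gaussian GLM of malignant-sample telomere content on (ΔA, ΔB).
   All p-values are pooled into one vector and controlled by the
   Benjamini–Hochberg step-up rule at FDR 0.1. Pair (A, B) is a *hit* —
   "A transcriptionally activates B on the telomere-maintenance axis" — when
   all three tests survive B-H and both OLS slopes are positive.
3. **Telomere association** — simple and multiple OLS of Δtelomere and of
   malignant-sample telomere content on a panel of gene deltas
   (NELL2, PAX7, RAD52, H2AFX, RAD51 by default).
4. **Dichotomized survival** — patients split by Δfactor > 0 vs Δfactor ≤ 0
   (factor = a gene or telomere content); overall and metastasis-free survival
   compared by univariate Cox regression (Breslow ties; Efron by flag), with
   Kaplan–Meier curves and a logistic regression against high FNCLCC grade.
5. **Telomere content from reads** — a simplified GC-corrected estimator:
   reads with ≥ t non-consecutive TTAGGG repeats (either strand) are
   intratelomeric, and
   `tel_content = intratel_reads × 1e6 / reads with GC in [0.48, 0.52]`.

A seeded synthetic-cohort generator plants all of these signals (DEG shifts,
a linear Δ-scale cascade, a gene→telomere effect, group-dependent exponential
survival) so the full pipeline is testable without any external data.

## Worked example

```python
from telocascade import CascadeScreen, CoxSurvival, DegScreen, compute_deltas
from telocascade.simulate import paper_shaped_config, simulate_cohort

cohort, truth = simulate_cohort(paper_shaped_config(seed=1))
deltas = compute_deltas(cohort)

degs = DegScreen(deltas).fit()
screen = CascadeScreen.from_preset(deltas, "deg_pax", glm_spec="joint").fit()
print(screen.summary())
print(CoxSurvival(deltas, cohort.clinical, "telomere", "OS").fit().summary())
```

prints

```
Transcriptional-cascade screen
  pairs tested: 198 (skipped: 0)
  pooled p-values under B-H: 594 (pooling=pooled, FDR=0.1, glm=joint)
  hits: 1
    NELL2 -> PAX7: dB=0.344 (p=1.81e-10), targetB=0.356 (p=3.81e-05), glmB=12.552 (p=6.39e-05)
OS ~ telomere increased vs not: HR = 4.199 (1.037 to 16.999), Wald p = 0.044 [n = 8/11, events = 7/4, ties=breslow]
```

Reading this: the 22 selected DEGs × 9 PAX genes give 198 ordered pairs and
594 pooled p-values; the only pair passing the joint rule is the planted
NELL2→PAX7 edge, whose ΔPAX7-on-ΔNELL2 slope (0.344) recovers the generating
slope 0.335. Patients whose telomere content rose during transformation die
at ~4.2× the hazard of those whose content did not rise.

The same workflow runs from the shell on TSV inputs:

```bash
telocascade simulate --preset suite --seed 1 --out fixtures/
telocascade run --config pipeline.cfg --out results/
telocascade telcontent sample.fastq --out telomere.tsv
```

`telocascade run` writes every stage table (`degs.tsv`, `edges_stage1.tsv`,
`edges_stage2.tsv`, `hits.tsv`, `association.tsv`, `survival.tsv`, `km.tsv`),
a run log, and `report.txt`.

## Layout

- `src/telocascade/cohort.py` — data model, TSV I/O, log transform, deltas, summaries
- `src/telocascade/simulate.py` — seeded synthetic-cohort generator and fixtures
- `src/telocascade/deg.py` — paired DEG screen
- `src/telocascade/screen.py` — composite cascade screen and B-H control
- `src/telocascade/association.py` — telomere association regressions
- `src/telocascade/survival.py` — dichotomized Cox/KM/logistic analyses
- `src/telocascade/telomere.py` — read-level GC-corrected telomere content
- `src/telocascade/pipeline.py`, `cli.py` — orchestration and the `telocascade` CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
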
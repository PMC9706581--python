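# uroscore

Molecular subtyping, immunosuppressive-macrophage signature scoring, and
immune-evasion modelling of immune-checkpoint-inhibitor (ICI) response in
urothelial carcinoma.

## The problem

Anti-PD-L1 therapy helps only a minority of patients with advanced
urothelial carcinoma, and expression biomarkers behave inconsistently
across the luminal/basal intrinsic subtypes. A signature of
immunosuppressive tumour-associated macrophages (here called the
**Macro-C3 score**) tracks response to PD-L1 blockade in luminal-leaning
tumours — but in basal-leaning tumours the same macrophages mark immune
*evasion*, and the score loses (indeed reverses) its predictive meaning.
`uroscore` implements the scoring-and-prediction machinery around that
observation for bulk transcriptomes, together with the supporting
single-cell rules (quality control, a high-confidence differential
expression filter, compartment-relative cell proportions, and a
permutation-based ligand–receptor interaction screen), plus synthetic-data
generators so the whole pipeline is testable without any external cohort.

## The model

For a cohort of N samples with TPM expression, four signatures are scored
per sample by single-sample gene-set enrichment (ssGSEA, rank-weighted
running sum with exponent α = 0.25, on log2(TPM+1)): the luminal and basal
halves of the BASE47 panel (L, B), T-cell cytotoxicity (C), and Macro-C3
(M). The subtype axis is

    r_i = ln( b_i / l_i ),

with b, l min–max rescaled onto [0.01, 1] so the ratio is defined. C and M
are z-scored (sample SD) and each regressed on r by ordinary least squares,
giving lines L_C and L_M that intersect at (a, b). The threshold a splits
the cohort: samples with r_i < a are in the regime where cytotoxicity
dominates and M predicts response; samples with r_i ≥ a are in the evasion
regime. The **piecewise ICI response score** is

    score_i = m_i          if r_i < a
    score_i = min_j m_j    if r_i ≥ a,

i.e. evasion-regime samples are floored to the cohort-minimum Macro-C3
score. A responder-fraction curve over 256 evenly spaced cutoffs of r and
ROC/AUC (Mann–Whitney tie handling), quartile stratification and Fisher's
exact test support the evaluation. A published threshold fitted on another
cohort can be supplied with `--threshold` instead of the internally fitted
intersection.

A geometric identity worth knowing: because both responses are z-scored,
each OLS line passes through (mean(r), 0), so the fitted intersection is
always a = mean(r), b = 0 — the threshold is the cohort's mean subtype
axis.

## Worked example

```python
from uroscore import (BulkSimConfig, generate_bulk_cohort,
                      score_cohort, evaluate_simulated)

cohort = generate_bulk_cohort(BulkSimConfig(n_samples=400, seed=1))
res = score_cohort(cohort.expression, cohort.signatures)
print(f"fitted lines: Z(C) = {res.fit.slope_c:.3f} r + {res.fit.intercept_c:.3f}, "
      f"Z(M) = {res.fit.slope_m:.3f} r + {res.fit.intercept_m:.3f}")
print(f"intersection: a = {res.fit.a:.3f}, b = {res.fit.b:.3f}  (n = {res.fit.n_samples})")
print(res.prediction.rule_tag.value_counts().to_string())
print(evaluate_simulated(cohort).to_string(index=False))
```

prints

```
fitted lines: Z(C) = 0.615 r + 0.008, Z(M) = 0.636 r + 0.008
intersection: a = -0.013, b = -0.000  (n = 400)
below:macro_score    208
above:cohort_min     192
             score      auc  n_pos  n_neg
ici_response_score 0.781272    137    263
          macro_c3 0.356277    137    263
```

The simulated cohort ties response to the Macro-C3 signal only below the
latent threshold and keeps a flat low response rate above it. The fitted
threshold lands at the cohort-mean log(basal/luminal) (−0.013, vs a
generating threshold at the axis centre); 208 samples are scored by their
Macro-C3 score and 192 are floored to the cohort minimum. The piecewise
score reaches AUC 0.78 while the raw Macro-C3 score — dragged down by
high-scoring evasion-regime samples that do not respond — falls below 0.5.

The same steps run from the shell:

```
uroscore simulate bulk --seed 1 --out cohort/
uroscore score --expr cohort/expression.tsv --gmt cohort/signatures.gmt --out scores.tsv
uroscore fit-evasion --expr cohort/expression.tsv --gmt cohort/signatures.gmt --out fit.json
uroscore predict --expr cohort/expression.tsv --gmt cohort/signatures.gmt --fit fit.json --out pred.tsv
```

Single-cell subcommands (`qc`, `degs`, `proportions`, `lr-screen`) operate
on MTX bundles with `features.tsv`/`barcodes.tsv`/`cells.tsv` sidecars;
`uroscore simulate sc` writes one.

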
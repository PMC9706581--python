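# Methods

This note documents the models, rules and numerical choices implemented
in `uroscore`, the assumptions behind the synthetic-data generators, and
the limits of what the tests demonstrate.

## Signature scoring

**ssGSEA.** For each sample the N genes are ranked by expression,
descending, with ties broken by gene name (a stable, platform-independent
order). The gene at position i from the top carries rank value N − i + 1.
With in-set size m and exponent α (default 0.25, exposed as a flag), the
enrichment score is the sum over the ranked list of the difference
between the normalised cumulative `rank^α` weight of in-set genes and the
cumulative count of out-of-set genes divided by N − m. Because weights
depend on expression only through ranks, the score is invariant to any
strictly increasing per-sample transform for every α (the test suite
asserts this at α = 0, where it holds trivially, and relies on it
implicitly elsewhere). Genes of a signature missing from the matrix are
dropped with a logged coverage warning; scoring errors out only when no
gene remains. No cross-sample normalisation is applied inside the scorer;
rescaling is a separate, explicit operation so every downstream number
carries a normalisation tag.

**Input scale.** "Log-normalised TPM" is implemented as log2(TPM + 1);
base and pseudocount are a package choice, and double transformation is
refused rather than silently absorbed.

**Rescaling and z-scoring.** The basal and luminal scores are min–max
mapped onto [ε, 1] with ε = 0.01 before the ratio, since raw enrichment
scores can be negative and log(b/l) requires positive arguments. The
cytotoxicity and Macro-C3 scores are z-scored with the sample (n − 1)
standard deviation; the intersection threshold is invariant to the n vs
n − 1 choice as long as both responses use the same convention, which the
single `zscore` implementation enforces.

## Subtype axis and calls

The axis is r = ln(basal/luminal) of the rescaled scores (natural log; a
module constant makes the base explicit). Subtype calls cluster samples
on the BASE47 sub-matrix — genes z-scored, sample distance 1 − Pearson,
average linkage, cut at k = 2 — and name the cluster with the higher mean
basal enrichment "basal". Distance and linkage are conventions (the most
common for expression clustering) and are exposed as arguments. The
three-way scheme overlays clinical stage: non-muscle-invasive samples are
labelled NMI regardless of cluster. For cohorts without stage a
nearest-centroid fallback against a labelled reference is provided and
tagged as such in the output.

## The immune-evasion model

Z(C) and Z(M) are each regressed on r by OLS; the intersection
(a, b) of the two lines defines the cohort threshold. Numerically,
a = (intercept_M − intercept_C)/(slope_C − slope_M); slopes closer than
1e-12 raise a parallel-lines error. Because both responses are z-scored,
each fitted line passes through (mean r, 0), so a equals the cohort-mean
log-ratio and b = 0 up to rounding — the model's threshold is the cohort
centroid of the subtype axis, and the slope difference only determines
which score dominates on each side. The fit is implemented for arbitrary
response vectors, so the closed-form examples in the tests (non-z-scored
lines) exercise the general geometry.

The piecewise ICI response score keeps the Macro-C3 score for samples
with r < a (strict inequality) and assigns the cohort-wide minimum
Macro-C3 score to the rest; the minimum is taken over all samples, below-
threshold ones included. The responder-fraction curve uses 256 cutoffs
evenly spaced over the observed range of r and reports the *cumulative*
fraction of responders among samples at or below each cutoff — chosen
because it is self-checking (the value at the last cutoff must equal the
cohort responder rate exactly); a sliding-window variant (window = 0.2 of
the range) is available behind a flag. A threshold fitted elsewhere can
be supplied as an override and is never hard-coded.

No uncertainty interval on a is part of the method; a percentile
bootstrap utility is provided separately.

## Evaluation

AUC follows the Mann–Whitney concordance convention (ties credit 0.5),
computed from the full empirical ROC curve (every distinct threshold,
trapezoidal integration); an O(n²) pairwise-concordance oracle in the
test suite pins the equivalence. Quartiles cut at the empirical 25/50/75
percentiles with boundary ties assigned to the lower quartile, so the
Q1-vs-Q4 contrast is deterministic. Fisher's exact test is two-sided by
probability ordering; the reported odds ratio is the sample odds ratio
with a Haldane +0.5 correction when a cell is zero (the conditional MLE
is deliberately not computed).

## Single-cell rules

**QC.** Genes expressed (count > 0) in more than 3 cells are kept first;
cell filters then act on the gene-filtered matrix: a cell is removed if
it has ≤ 200 expressed genes, > 5000 expressed genes, or a mitochondrial
UMI fraction > 0.25 (boundaries: exactly 200 removed, exactly 5000 kept,
exactly 0.25 kept). The order of the two filter families is a choice;
the QC report also records what the cell rules would have removed on the
unfiltered matrix so order sensitivity is visible. Mitochondrial genes
are identified by a configurable symbol prefix (default `MT-`).

**High-confidence DEGs.** Operating on per-sample mean log2-scale
expression, a gene passes for a subtype only if *every* sample of that
subtype exceeds the other subtype's average by more than 0.8 log2 fold
change — an all-samples rule that prevents one dominant tumour from
driving a subtype marker. Whether the means are raw or per-sample
normalised is up to the caller; log-normalised means are assumed and the
rule is antisymmetric for any positive threshold. Upstream differential
testing is out of scope; candidate genes are an input.

**Proportions.** The share of a target cluster within a compartment is
computed per sample; samples with fewer than 100 compartment cells are
flagged excluded rather than dropped silently.

## Ligand–receptor screen

Interaction strength between a sender and receiver cluster is the
arithmetic mean of the mean log-normalised ligand expression in the
sender and receptor expression in the receiver (per-cell library-size
normalisation to 10,000 counts, then log1p). A pair is scored only if
ligand and receptor are each expressed in more than 10% of the relevant
cluster's cells. Significance is empirical over 1,000 joint reshuffles of
the cluster labels by default, with the add-one correction
p = (1 + k)/(1 + n_perm) so p is never zero; a within-sample stratified
shuffle and an exhaustive enumeration mode (for very small bundles, used
as ground truth in tests) are available. No multiple-testing correction
is applied by default; Benjamini–Hochberg is available. The
interaction-vs-exhaustion screen reports per-pair Pearson r with
two-sided t-distribution p values and classifies pairs as significant
positive/negative at α = 0.05, skipping constant-strength pairs.

## Synthetic data: what it emulates and what it does not

**Bulk cohorts.** A latent basal axis t ~ U(−1, 1) drives expression on
the log2 scale: basal genes rise (+1·t by default) and luminal genes fall
along t; Macro-C3 genes rise with slope 1.4 and cytotoxicity genes with
slope 0.7, so after z-scoring the Macro-C3 regression line is the steeper
of the two; gene baselines are N(5, 1) and i.i.d. Gaussian noise
(SD 0.3) is added before exponentiation and column rescaling to TPM
(sum 10^6). Rank-based scoring downstream needs only this monotone
structure. Response is Bernoulli with probability
sigmoid(logit(p₀) + λ·(m_true − m_min)) below the latent threshold and
the flat baseline p₀ above it, with p₀ = 0.15 (comparable to response
rates reported for anti-PD-L1 therapy in metastatic urothelial
carcinoma) and link strength λ = 3. Anchoring the logistic at the bottom
of the below-threshold range makes the above-threshold samples both
high-scoring and rarely responding — the evasion premise — and λ = 0
collapses the probability to p₀ everywhere, giving exact label
independence for null calibration. The generating threshold defaults to
0, the centre of the latent axis, because the model's fitted threshold is
pinned to the cohort-mean axis (see above): the centre is the one value
the procedure can identify, and recovery is asserted after mapping the
fitted threshold back to the latent scale through the truth table. Two
generator fields (the subtype slope and the baseline response rate) are
package additions needed to realise this structure. Effect sizes are
chosen for test power, not biological realism; the generator has no
batch effects, no gene–gene correlation beyond the shared axis, and no
heavy-tailed noise, so passing tests demonstrate correctness of the
machinery, not performance on real cohorts.

**Single-cell bundles.** Negative-binomial counts (dispersion 0.5,
log-normal library sizes, σ = 0.3), cluster markers boosted 8-fold in
their own cluster, a configurable fraction of `MT-` genes with elevated
baseline, and ligand/receptor genes whose expressing-cell fraction per
cluster is set exactly (for gate tests). Low-quality cells are planted
relative to explicit QC thresholds: low-gene cells keep only the most
prevalent non-mitochondrial genes (so they violate exactly one rule and
survive the gene filter deterministically), high-gene cells express every
gene, and high-mito cells carry mitochondrial counts at twice the allowed
fraction. Ambient RNA, doublets and batch structure are not modelled.

## Problem sizes and tolerances

Closed-form checks use exact tolerances (1e-9 to 1e-12); the ssGSEA
oracle comparison uses 1e-10 over 100 random 20×5 instances. Stochastic
checks use 400-sample cohorts over 20 seeds (threshold recovery within
0.05 mean absolute error; piecewise-vs-raw AUC wins in ≥ 18/20), 50 seeds
for null AUC calibration ([0.45, 0.55]), and 200 null bundles for
permutation-p super-uniformity at α ∈ {0.05, 0.1} with a 99% Monte-Carlo
margin. Exhaustive enumerations cover all 2×2 tables with total ≤ 30 and
all 20 label assignments of a 6-cell two-cluster bundle. These sizes were
chosen so the full suite runs in about half a minute on one core.

## Known limitations

- The fitted threshold is identifiable only as the cohort-mean subtype
  axis under exact z-scoring; thresholds published for other cohorts
  reflect their scoring conventions and are accepted only as overrides.
- Raw enrichment scores depend on cohort composition through the min–max
  rescaling; scores are therefore comparable within a cohort, not across
  cohorts.
- The TIDE comparator is never computed internally; it is ingested as an
  extra score column when supplied.
- Survival analysis, clustering/integration/annotation of single cells,
  and deconvolution are out of scope by design.
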
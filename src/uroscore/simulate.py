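"""Synthetic cohorts with the statistical structure the analysis assumes.

Bulk cohorts: each sample carries a latent basal-differentiation axis
``t`` drawn uniform on [-1, 1].  Basal-signature genes increase and
luminal-signature genes decrease with ``t``; Macro-C3 and cytotoxicity
signature genes increase with their configured slopes.  Expression is
generated on the log2 scale (Gaussian noise around the signal means),
exponentiated, and column-rescaled to TPM.  Response to PD-L1 blockade
is tied to the true Macro-C3 signal only below a latent threshold:
below it the responder probability is a logistic function of the true
Macro-C3 signal (anchored at the baseline rate), above it the
probability is the constant baseline — so response is decoupled from
the score exactly where the immune-evasion model says it should be.

Because both signature scores are z-scored before the two regressions,
the fitted intersection lands at the cohort-mean log(basal/luminal);
the generating threshold therefore defaults to the centre of the
latent axis, the one point the model can identify.

Single-cell bundles: negative-binomial counts (dispersion 0.5,
log-normal library sizes) with cluster-specific marker genes,
designated mitochondrial genes, ligand/receptor genes expressed in
configurable fractions of cells per cluster, and planted low-quality
cells violating each QC rule by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .lr_screen import LRPair
from .sc_rules import SingleCellBundle, write_bundle  # noqa: F401  (re-export)
from .signatures import ExpressionMatrix, GeneSet, write_gmt

#: background genes required beyond the signature genes
MIN_BACKGROUND_GENES = 50
#: canonical signature names used throughout the package
SIG_LUMINAL = "BASE47-luminal"
SIG_BASAL = "BASE47-basal"
SIG_MACRO = "Macro-C3"
SIG_CYTOTOX = "cytotoxicity"


# ---------------------------------------------------------------------------
# signature sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureSet:
    """The four named gene sets driving the pipeline, with provenance."""

    luminal: GeneSet
    basal: GeneSet
    macro: GeneSet
    cytotox: GeneSet
    provenance: str = "synthetic"

    def __iter__(self):
        return iter((self.luminal, self.basal, self.macro, self.cytotox))

    @property
    def all_genes(self) -> list[str]:
        return [g for s in self for g in s.genes]

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(list(self), path)


def generate_signature_sets(
    n_luminal: int = 24,
    n_basal: int = 23,
    n_macro: int = 10,
    n_cytotox: int = 8,
    seed: int = 0,
) -> SignatureSet:
    """Disjoint synthetic stand-ins for the BASE47 halves, the Macro-C3
    signature, and the T-cell cytotoxicity signature.

    Gene symbols are drawn without replacement from a deterministic
    pool, so the four sets are disjoint and reproducible per seed.
    """
    counts = {"n_luminal": n_luminal, "n_basal": n_basal,
              "n_macro": n_macro, "n_cytotox": n_cytotox}
    for name, n in counts.items():
        if n < 2:
            raise ValueError(f"{name} must be >= 2, got {n}")
    total = sum(counts.values())
    rng = np.random.default_rng(seed)
    pool = np.array([f"G{i:05d}" for i in rng.permutation(10 * total)])
    cuts = np.cumsum([n_luminal, n_basal, n_macro, n_cytotox])
    lum, bas, mac, cyt = np.split(pool[: cuts[-1]], cuts[:-1])
    return SignatureSet(
        luminal=GeneSet(SIG_LUMINAL, tuple(lum), "synthetic luminal half of BASE47"),
        basal=GeneSet(SIG_BASAL, tuple(bas), "synthetic basal half of BASE47"),
        macro=GeneSet(SIG_MACRO, tuple(mac), "synthetic immunosuppressive macrophage signature"),
        cytotox=GeneSet(SIG_CYTOTOX, tuple(cyt), "synthetic T-cell cytotoxicity signature"),
        provenance=f"generate_signature_sets(seed={seed})",
    )


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

@dataclass
class BulkSimConfig:
    """Generating parameters for a synthetic bulk expression cohort."""

    n_samples: int = 400
    n_genes: int = 200
    threshold_a_true: float = 0.0  # on the latent axis; its centre (see module docs)
    slope_cytotox: float = 0.7  # weaker than the Macro-C3 slope, so the
    slope_macro: float = 1.4    # z-scored Macro-C3 line is the steeper one
    slope_subtype: float = 1.0  # basal genes +, luminal genes - along the axis
    response_link_strength: float = 3.0
    baseline_response_rate: float = 0.15
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self, n_signature_genes: int) -> None:
        if self.n_samples < 8:
            raise ValueError(f"n_samples must be >= 8, got {self.n_samples}")
        needed = n_signature_genes + MIN_BACKGROUND_GENES
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes = {self.n_genes} too small: need >= {needed} "
                f"({n_signature_genes} signature genes + {MIN_BACKGROUND_GENES} background)"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.response_link_strength < 0:
            raise ValueError("response_link_strength must be >= 0")
        if not 0 < self.baseline_response_rate < 1:
            raise ValueError("baseline_response_rate must be in (0, 1)")


@dataclass
class SimulatedCohort:
    """Expression + signatures + the generating truth table."""

    expression: ExpressionMatrix  # genes x samples, TPM
    signatures: SignatureSet
    truth: pd.DataFrame  # latent_axis, macro_true, cytotox_true, responder_prob, responder
    config: BulkSimConfig


def generate_bulk_cohort(
    config: BulkSimConfig,
    signatures: SignatureSet | None = None,
) -> SimulatedCohort:
    """Simulate a TPM cohort with the structure described in the module
    docstring; identical config (seed included) gives identical output."""
    if signatures is None:
        signatures = generate_signature_sets(seed=config.seed)
    sig_genes = signatures.all_genes
    if len(set(sig_genes)) != len(sig_genes):
        raise ValueError("signature sets overlap")
    config.validate(len(sig_genes))
    rng = np.random.default_rng(config.seed)

    n_bg = config.n_genes - len(sig_genes)
    bg_genes = [f"BG{i:05d}" for i in range(n_bg)]
    genes = pd.Index(sig_genes + bg_genes)
    samples = pd.Index([f"S{i:04d}" for i in range(config.n_samples)])

    t = rng.uniform(-1.0, 1.0, size=config.n_samples)

    # per-gene slope along the latent axis
    slope = pd.Series(0.0, index=genes)
    slope.loc[list(signatures.basal.genes)] = config.slope_subtype
    slope.loc[list(signatures.luminal.genes)] = -config.slope_subtype
    slope.loc[list(signatures.macro.genes)] = config.slope_macro
    slope.loc[list(signatures.cytotox.genes)] = config.slope_cytotox

    baseline = rng.normal(5.0, 1.0, size=config.n_genes)
    log2_expr = (
        baseline[:, None]
        + slope.to_numpy()[:, None] * t[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    )
    tpm = np.exp2(log2_expr)
    tpm = tpm / tpm.sum(axis=0, keepdims=True) * 1e6

    macro_true = config.slope_macro * t
    cytotox_true = config.slope_cytotox * t
    a = config.threshold_a_true
    below = t < a
    # logistic link anchored so the LOWEST below-threshold Macro-C3 signal
    # responds at the baseline rate and response rises from there; above the
    # threshold the rate is the flat baseline, so those samples respond both
    # independently of their (high) Macro-C3 score and rarely.  link = 0
    # collapses to the baseline everywhere (labels independent of all scores).
    anchor = config.slope_macro * -1.0  # Macro-C3 signal at the bottom of the axis
    logit0 = np.log(config.baseline_response_rate / (1 - config.baseline_response_rate))
    eta = logit0 + config.response_link_strength * (macro_true - anchor)
    prob = np.where(below, 1.0 / (1.0 + np.exp(-eta)), config.baseline_response_rate)
    responder = (rng.uniform(size=config.n_samples) < prob).astype(int)

    truth = pd.DataFrame({
        "latent_axis": t,
        "macro_true": macro_true,
        "cytotox_true": cytotox_true,
        "below_threshold": below,
        "responder_prob": prob,
        "responder": responder,
        "threshold_a_true": a,
        "seed": config.seed,
    }, index=samples)

    expr = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=genes, columns=samples),
        scale_tag="tpm",
    )
    return SimulatedCohort(expression=expr, signatures=signatures,
                           truth=truth, config=config)


def map_threshold_to_latent(truth: pd.DataFrame, log_ratio: pd.Series, a: float) -> float:
    """Map a fitted log-ratio threshold back onto the latent axis.

    Uses the OLS calibration t = alpha + beta * r from the truth table,
    evaluated at the fitted threshold.
    """
    r = log_ratio.loc[truth.index].to_numpy(dtype=float)
    t = truth["latent_axis"].to_numpy(dtype=float)
    beta, alpha = np.polyfit(r, t, deg=1)
    return float(alpha + beta * a)


def write_bulk_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """expression.tsv (genes x samples), truth.tsv, signatures.gmt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.expression.values.to_csv(out / "expression.tsv", sep="\t")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t")
    cohort.signatures.to_gmt(out / "signatures.gmt")


# ---------------------------------------------------------------------------
# single-cell bundle
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and dispersion phi so that
    variance = mean + phi * mean^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_single_cell_bundle(
    n_clusters: int = 3,
    cells_per_cluster: int = 100,
    n_genes: int = 300,
    frac_mito_genes: float = 0.05,
    lr_pairs: int | Sequence[LRPair] = 3,
    seed: int = 0,
    n_samples: int = 2,
    marker_genes_per_cluster: int = 5,
    dispersion: float = 0.5,
    lr_expr_frac: float | Mapping[tuple[str, str], float] = 0.4,
    planted_low_gene_cells: int = 0,
    planted_high_gene_cells: int = 0,
    planted_high_mito_cells: int = 0,
    qc_thresholds: tuple[int, int, float] = (200, 5000, 0.25),
) -> tuple[SingleCellBundle, list[LRPair], dict[str, list[str]]]:
    """Clustered NB counts with markers, mito genes, L/R genes and
    planted QC violations.

    ``lr_expr_frac`` sets the fraction of cells expressing each ligand/
    receptor gene, either globally or per ``(gene, cluster)``.  Planted
    low-quality cells are appended after the regular cells and violate
    one QC rule each, judged against ``qc_thresholds`` (min expressed
    genes, max expressed genes, max mitochondrial UMI fraction).

    Returns the bundle, the LR panel, and a dict mapping each planted
    violation ("low_genes", "high_genes", "high_mito") to its barcodes.
    """
    if n_clusters < 2:
        raise ValueError(f"n_clusters must be >= 2, got {n_clusters}")
    if cells_per_cluster < 3:
        raise ValueError(f"cells_per_cluster must be >= 3, got {cells_per_cluster}")
    min_genes, max_genes, max_mito = qc_thresholds
    if planted_high_gene_cells > 0 and n_genes <= max_genes:
        raise ValueError(
            "cannot plant high-gene cells: n_genes must exceed the max_genes threshold"
        )
    rng = np.random.default_rng(seed)

    n_mito = max(1, round(frac_mito_genes * n_genes))
    if isinstance(lr_pairs, int):
        panel = [LRPair(f"LIG{i:02d}", f"REC{i:02d}") for i in range(lr_pairs)]
    else:
        panel = list(lr_pairs)
    lig_genes = [p.ligand for p in panel]
    rec_genes = [p.receptor for p in panel]
    n_other = n_genes - n_mito - len(lig_genes) - len(rec_genes)
    if n_other < n_clusters * marker_genes_per_cluster:
        raise ValueError("n_genes too small for the requested mito/LR/marker genes")
    genes = pd.Index(
        [f"MT-G{i:03d}" for i in range(n_mito)]
        + lig_genes + rec_genes
        + [f"SCG{i:05d}" for i in range(n_other)]
    )

    clusters = [f"C{k}" for k in range(n_clusters)]
    n_regular = n_clusters * cells_per_cluster
    cell_cluster = np.repeat(clusters, cells_per_cluster)

    # baseline rates; mito genes get a higher rate so normal cells carry a
    # plausible (but sub-threshold) mitochondrial fraction
    base_rate = rng.lognormal(mean=0.0, sigma=0.6, size=n_genes)
    base_rate[:n_mito] *= 3.0
    lib = rng.lognormal(mean=0.0, sigma=0.3, size=n_regular)

    mean = base_rate[:, None] * lib[None, :]
    # cluster-specific marker genes, boosted in their own cluster
    marker_map: dict[str, list[str]] = {}
    offset = n_mito + len(lig_genes) + len(rec_genes)
    for k, cl in enumerate(clusters):
        rows = slice(offset + k * marker_genes_per_cluster,
                     offset + (k + 1) * marker_genes_per_cluster)
        marker_map[cl] = list(genes[rows])
        mean[rows][:, cell_cluster == cl] *= 8.0
    counts = _nb_counts(rng, mean, dispersion).astype(np.int64)

    # enforce the configured expression fraction for each L/R gene per cluster
    def frac_for(gene: str, cluster: str) -> float:
        if isinstance(lr_expr_frac, Mapping):
            return lr_expr_frac.get((gene, cluster), 0.4)
        return lr_expr_frac

    for gene in lig_genes + rec_genes:
        gi = genes.get_loc(gene)
        for cl in clusters:
            idx = np.flatnonzero(cell_cluster == cl)
            f = frac_for(gene, cl)
            n_on = int(round(f * len(idx)))
            on = rng.choice(idx, size=n_on, replace=False) if n_on else np.array([], int)
            orig = counts[gi, on].copy()
            counts[gi, idx] = 0
            counts[gi, on] = np.maximum(orig, 1)

    # planted QC violations, appended after the regular cells
    planted_cols: list[np.ndarray] = []
    planted_clusters: list[str] = []
    planted: dict[str, list[str]] = {"low_genes": [], "high_genes": [], "high_mito": []}
    # genes most widely expressed among regular cells survive the gene
    # filter; mito genes excluded so low-gene cells violate only one rule
    prevalence = (counts > 0).sum(axis=1).astype(float)
    prevalence[:n_mito] = -1
    prevalence_order = np.argsort(-prevalence)

    def new_barcode(tag: str, i: int) -> str:
        return f"PLANT-{tag}-{i}"

    for i in range(planted_low_gene_cells):
        col = np.zeros(n_genes, dtype=np.int64)
        keep = prevalence_order[: max(1, min_genes // 2)]
        col[keep] = 5
        planted_cols.append(col)
        planted_clusters.append(clusters[0])
        planted["low_genes"].append(new_barcode("LOW", i))
    for i in range(planted_high_gene_cells):
        col = np.ones(n_genes, dtype=np.int64)
        planted_cols.append(col)
        planted_clusters.append(clusters[0])
        planted["high_genes"].append(new_barcode("HIGH", i))
    for i in range(planted_high_mito_cells):
        col = _nb_counts(rng, base_rate, dispersion).astype(np.int64)
        col[:n_mito] = 0
        non_mito_total = col.sum()
        # mito counts set to twice the allowed share of the final total
        share = min(2 * max_mito, 0.9)
        target = int(np.ceil(share * non_mito_total / (1 - share))) + n_mito
        col[:n_mito] = target // n_mito + 1
        planted_cols.append(col)
        planted_clusters.append(clusters[0])
        planted["high_mito"].append(new_barcode("MITO", i))

    if planted_cols:
        counts = np.hstack([counts, np.column_stack(planted_cols)])
        cell_cluster = np.concatenate([cell_cluster, planted_clusters])
    barcodes = pd.Index(
        [f"CELL{i:05d}" for i in range(n_regular)]
        + planted["low_genes"] + planted["high_genes"] + planted["high_mito"]
    )
    cell_sample = pd.Series(
        [f"SC_SAMPLE{i % n_samples}" for i in range(len(barcodes))], index=barcodes
    )
    gene_flags = pd.DataFrame({
        "mitochondrial": genes.str.startswith("MT-"),
        "ligand": genes.isin(lig_genes),
        "receptor": genes.isin(rec_genes),
    }, index=genes)
    bundle = SingleCellBundle(
        counts=sparse.csr_matrix(counts),
        genes=genes,
        cells=barcodes,
        cell_cluster=pd.Series(cell_cluster, index=barcodes),
        cell_sample=cell_sample,
        gene_flags=gene_flags,
    )
    return bundle, panel, planted
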
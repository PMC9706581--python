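"""Single-cell rule-based procedures: QC filtering, the high-confidence
DEG filter, and compartment-relative cell proportions.

These are the concrete per-study rules applied to droplet scRNA-seq
count matrices:

* quality control — genes kept when expressed (count > 0) in more than
  ``min_cells_per_gene`` cells; cells then kept when they have strictly
  more than ``min_genes`` expressed genes, at most ``max_genes``, and a
  mitochondrial UMI fraction of at most ``max_mito_frac``;
* high-confidence differential expression — a gene passes for a subtype
  only if EVERY sample of that subtype shows a log2 fold change above
  the threshold over the other subtype's average, which guards against
  a single dominant tumour driving a call;
* relative proportions — the share of a target cluster within a
  compartment (e.g. an immunosuppressive macrophage cluster within all
  myeloid cells), per sample, with small samples flagged excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

#: gene-symbol prefix identifying mitochondrial genes
MITO_PREFIX = "MT-"
#: samples with fewer compartment cells than this are flagged excluded
MIN_CELLS_PER_SAMPLE = 100


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class SingleCellBundle:
    """Sparse genes x cells counts with cell and gene annotations."""

    counts: sparse.csr_matrix  # genes x cells, nonnegative integers
    genes: pd.Index
    cells: pd.Index
    cell_cluster: pd.Series
    cell_sample: pd.Series
    gene_flags: pd.DataFrame  # boolean columns: mitochondrial, ligand, receptor

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("counts shape does not match gene/cell annotations")
        for ann in (self.cell_cluster, self.cell_sample):
            missing = [c for c in self.cells if c not in ann.index]
            if missing:
                raise ValueError(f"cells without annotation: {missing[:5]}...")
        if self.counts.nnz and (self.counts.data < 0).any():
            raise ValueError("negative counts")
        for col in ("mitochondrial", "ligand", "receptor"):
            if col not in self.gene_flags.columns:
                raise ValueError(f"gene_flags missing column {col!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset(self, gene_mask=None, cell_mask=None) -> "SingleCellBundle":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        genes = self.genes[gm]
        cells = self.cells[cm]
        return SingleCellBundle(
            counts=self.counts[gm][:, cm],
            genes=genes,
            cells=cells,
            cell_cluster=self.cell_cluster.loc[cells],
            cell_sample=self.cell_sample.loc[cells],
            gene_flags=self.gene_flags.loc[genes],
        )


def flag_genes(genes: pd.Index, ligands: Sequence[str] = (),
               receptors: Sequence[str] = (), mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Build the gene_flags frame from a symbol prefix and L/R lists."""
    return pd.DataFrame({
        "mitochondrial": genes.str.startswith(mito_prefix),
        "ligand": genes.isin(list(ligands)),
        "receptor": genes.isin(list(receptors)),
    }, index=genes)


# ---------------------------------------------------------------------------
# MTX I/O
# ---------------------------------------------------------------------------

def write_bundle(bundle: SingleCellBundle, out_dir: str | Path) -> None:
    """matrix.mtx + features.tsv/barcodes.tsv sidecars + cell annotation TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(bundle.counts))
    bundle.gene_flags.reset_index(names="gene").to_csv(
        out / "features.tsv", sep="\t", index=False)
    pd.Series(bundle.cells, name="barcode").to_csv(
        out / "barcodes.tsv", sep="\t", index=False)
    pd.DataFrame({
        "barcode": bundle.cells,
        "cluster": bundle.cell_cluster.loc[bundle.cells].to_numpy(),
        "sample": bundle.cell_sample.loc[bundle.cells].to_numpy(),
    }).to_csv(out / "cells.tsv", sep="\t", index=False)


def read_bundle(in_dir: str | Path) -> SingleCellBundle:
    src = Path(in_dir)
    counts = sparse.csr_matrix(spio.mmread(src / "matrix.mtx"))
    feats = pd.read_csv(src / "features.tsv", sep="\t").set_index("gene")
    cells = pd.read_csv(src / "cells.tsv", sep="\t")
    return SingleCellBundle(
        counts=counts,
        genes=feats.index,
        cells=pd.Index(cells["barcode"]),
        cell_cluster=cells.set_index("barcode")["cluster"],
        cell_sample=cells.set_index("barcode")["sample"],
        gene_flags=feats[["mitochondrial", "ligand", "receptor"]].astype(bool),
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Counts of records removed per rule, for both filter orders.

    The shipped order applies the gene filter first, then the three
    cell rules on the gene-filtered matrix; ``alt_removed`` records how
    many cells each rule would remove were the cell filters applied on
    the unfiltered matrix, so order sensitivity is visible.
    """

    genes_removed: int
    cells_removed_low_genes: int
    cells_removed_high_genes: int
    cells_removed_high_mito: int
    alt_removed: dict[str, int]
    n_genes_kept: int
    n_cells_kept: int


def _cell_rule_masks(bundle: SingleCellBundle, min_genes: int, max_genes: int,
                     max_mito_frac: float):
    """Boolean removal masks for the three cell rules (strict boundaries:
    exactly ``min_genes`` expressed genes is removed, exactly
    ``max_genes`` is kept, mito fraction exactly at the cap is kept)."""
    expressed = (bundle.counts > 0).sum(axis=0).A1
    total = np.asarray(bundle.counts.sum(axis=0)).ravel()
    mito = np.asarray(
        bundle.counts[bundle.gene_flags["mitochondrial"].to_numpy()].sum(axis=0)
    ).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    low = expressed <= min_genes
    high = expressed > max_genes
    hi_mito = mito_frac > max_mito_frac
    return low, high, hi_mito


def qc_filter(
    bundle: SingleCellBundle,
    min_genes: int = 200,
    max_genes: int = 5000,
    max_mito_frac: float = 0.25,
    min_cells_per_gene: int = 3,
) -> tuple[SingleCellBundle, QCReport]:
    """Gene filter first, then the three cell rules on the filtered matrix."""
    if not bundle.gene_flags["mitochondrial"].any() and bundle.n_genes > 0:
        raise ValueError("no mitochondrial gene annotation; cannot apply the mito rule")
    if bundle.n_cells == 0 or bundle.n_genes == 0:
        report = QCReport(0, 0, 0, 0,
                          {"low_genes": 0, "high_genes": 0, "high_mito": 0},
                          bundle.n_genes, bundle.n_cells)
        return bundle, report

    # what the cell rules would do on the raw matrix (order sensitivity)
    alt = _cell_rule_masks(bundle, min_genes, max_genes, max_mito_frac)
    alt_removed = {
        "low_genes": int(alt[0].sum()),
        "high_genes": int(alt[1].sum()),
        "high_mito": int(alt[2].sum()),
    }

    cells_per_gene = (bundle.counts > 0).sum(axis=1).A1
    keep_genes = cells_per_gene > min_cells_per_gene
    filtered = bundle.subset(gene_mask=keep_genes)

    low, high, hi_mito = _cell_rule_masks(filtered, min_genes, max_genes, max_mito_frac)
    keep_cells = ~(low | high | hi_mito)
    out = filtered.subset(cell_mask=keep_cells)
    report = QCReport(
        genes_removed=int((~keep_genes).sum()),
        cells_removed_low_genes=int(low.sum()),
        cells_removed_high_genes=int(high.sum()),
        cells_removed_high_mito=int(hi_mito.sum()),
        alt_removed=alt_removed,
        n_genes_kept=out.n_genes,
        n_cells_kept=out.n_cells,
    )
    return out, report


# ---------------------------------------------------------------------------
# high-confidence DEGs
# ---------------------------------------------------------------------------

@dataclass
class DEGRecord:
    gene: str
    direction: str  # the focal subtype
    per_sample_log2fc: dict[str, float]
    passed: bool


def high_confidence_degs(
    per_sample_mean_expr: pd.DataFrame,
    sample_subtype: Mapping[str, str] | pd.Series,
    threshold: float = 0.8,
) -> list[DEGRecord]:
    """Keep genes whose every focal-subtype sample beats the other
    subtype's average by more than ``threshold`` log2 fold change.

    ``per_sample_mean_expr`` is genes x samples of log2-scale mean
    expression; the fold change of sample s over the other subtype is
    simply ``expr[g, s] - mean(expr[g, other samples])``.
    """
    subtype = pd.Series(sample_subtype)
    missing = [s for s in per_sample_mean_expr.columns if s not in subtype.index]
    if missing:
        raise ValueError(f"samples without subtype annotation: {missing}")
    subtype = subtype.loc[per_sample_mean_expr.columns]
    groups = subtype.unique()
    if len(groups) != 2:
        raise ValueError(f"exactly 2 subtypes required, got {list(groups)}")
    for g in groups:
        if (subtype == g).sum() < 1:
            raise ValueError(f"subtype {g!r} has no samples")

    records: list[DEGRecord] = []
    for focal in groups:
        focal_cols = subtype.index[subtype == focal]
        other_cols = subtype.index[subtype != focal]
        other_avg = per_sample_mean_expr[other_cols].mean(axis=1)
        log2fc = per_sample_mean_expr[focal_cols].sub(other_avg, axis=0)
        passed = (log2fc > threshold).all(axis=1)
        for gene in per_sample_mean_expr.index:
            records.append(DEGRecord(
                gene=gene,
                direction=str(focal),
                per_sample_log2fc=log2fc.loc[gene].to_dict(),
                passed=bool(passed.loc[gene]),
            ))
    return records


def write_degs(records: Sequence[DEGRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "gene": r.gene,
            "direction": r.direction,
            "min_log2fc": min(r.per_sample_log2fc.values()),
            "passed": r.passed,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# relative proportions
# ---------------------------------------------------------------------------

def relative_proportion(
    bundle: SingleCellBundle,
    target_cluster: str,
    compartment_clusters: Sequence[str],
    min_cells: int = MIN_CELLS_PER_SAMPLE,
) -> pd.DataFrame:
    """Per-sample share of the target cluster within a compartment.

    Samples contributing fewer than ``min_cells`` compartment cells are
    flagged ``excluded`` (their fraction is still reported).
    """
    if target_cluster not in compartment_clusters:
        raise ValueError(
            f"target cluster {target_cluster!r} not in the compartment {list(compartment_clusters)}"
        )
    cluster = bundle.cell_cluster.loc[bundle.cells]
    sample = bundle.cell_sample.loc[bundle.cells]
    in_comp = cluster.isin(list(compartment_clusters))
    comp_n = sample[in_comp].value_counts()
    target_n = sample[in_comp & (cluster == target_cluster)].value_counts()
    samples = sorted(sample.unique())
    rows = []
    for s in samples:
        n = int(comp_n.get(s, 0))
        t = int(target_n.get(s, 0))
        rows.append({
            "sample": s,
            "n_compartment": n,
            "n_target": t,
            "fraction": t / n if n > 0 else np.nan,
            "excluded": n < min_cells,
        })
    return pd.DataFrame(rows).set_index("sample")
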
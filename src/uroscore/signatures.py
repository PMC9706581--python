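"""Gene-set I/O and single-sample enrichment scoring.

This module provides the scoring primitives used throughout the package:
GMT gene-set reading/writing, log-normalisation of TPM matrices,
single-sample GSEA (ssGSEA) enrichment scores, and the rescaling /
z-scoring steps that turn raw enrichment scores into the luminal (L),
basal (B), cytotoxicity (C) and Macro-C3 (M) score vectors consumed by
the subtype axis and the immune-evasion model.

The ssGSEA statistic implemented here is the classic rank-weighted
running-sum: per sample, genes are ranked by expression (descending);
the score is the sum, over the ranked list, of the difference between
the weighted in-set empirical CDF (weights ``rank**alpha``) and the
unweighted out-of-set ECDF.  Because the weights depend on expression
only through ranks, the score is invariant to any strictly increasing
per-sample transform of the expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("uroscore")

#: default exponent of the rank weights in the ssGSEA running sum
DEFAULT_ALPHA = 0.25
#: lower endpoint of the min-max rescaling (scores must be positive
#: before log(basal/luminal) can be taken)
RESCALE_EPS = 0.01


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene symbols."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        genes = tuple(self.genes)
        if len(genes) < 2:
            raise ValueError(f"gene set {self.name!r} needs >= 2 genes, got {len(genes)}")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale tag.

    ``scale_tag`` is ``"tpm"`` for nonnegative linear-scale values and
    ``"log"`` after :func:`log_normalize` (log2(TPM + 1)).
    """

    values: pd.DataFrame
    scale_tag: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("tpm", "log"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene names in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        if self.scale_tag == "tpm" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in a TPM-scale expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class ScoreVector:
    """Per-sample scores for one signature, with a normalisation tag."""

    name: str
    scores: pd.Series
    normalization_tag: str = "raw"
    coverage: float | None = None  # fraction of the gene set present in the matrix

    def __post_init__(self) -> None:
        if self.normalization_tag not in ("raw", "rescaled", "zscore"):
            raise ValueError(f"unknown normalization_tag {self.normalization_tag!r}")
        self.scores = self.scores.astype(float)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} tab-separated fields; "
                    "GMT requires name, description and >= 1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in seen:
                raise ValueError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            seen.add(name)
            sets.append(GeneSet(name=name, genes=tuple(genes), description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets to a GMT file; ``write_gmt`` then :func:`read_gmt` round-trips."""
    sets = list(sets)
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene set names")
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# expression I/O and normalisation
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, scale_tag: str = "tpm") -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV matrix (header row of sample IDs)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(values=df, scale_tag=scale_tag)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    expr.values.to_csv(path, sep=sep)


def log_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform; refuses to double-transform."""
    if expr.scale_tag != "tpm":
        raise ValueError("matrix is already log scale; refusing to log-transform twice")
    return ExpressionMatrix(values=np.log2(expr.values + 1.0), scale_tag="log")


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ranked_order(values: np.ndarray, gene_names: np.ndarray) -> np.ndarray:
    """Indices ordering genes by descending expression, ties by gene name.

    The stable name tiebreak makes scores identical across platforms and
    row orderings of the input matrix.
    """
    # lexsort: primary key last -> sort by (-value, name)
    return np.lexsort((gene_names, -values))


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    alpha: float = DEFAULT_ALPHA,
) -> ScoreVector:
    """Single-sample GSEA enrichment score of ``gene_set`` for every sample.

    Per sample the N genes are ranked by expression (descending, ties
    broken by gene name); the gene at position i carries rank value
    ``N - i``.  The score is::

        ES = sum_i [ P_in(i) - P_out(i) ]

    where ``P_in`` is the cumulative ``rank**alpha`` weight of in-set
    genes (normalised by the total in-set weight) and ``P_out`` the
    cumulative count of out-of-set genes divided by ``N - m``.

    Genes of the set absent from the matrix are dropped with a logged
    coverage warning; if none remain this is an error.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if expr.scale_tag != "log":
        raise ValueError("ssgsea_score expects a log-normalized matrix")
    present = [g for g in gene_set.genes if g in expr.genes]
    coverage = len(present) / len(gene_set)
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    if coverage < 1.0:
        logger.warning(
            "gene set %s: %d/%d genes present in matrix (coverage %.2f)",
            gene_set.name, len(present), len(gene_set), coverage,
        )

    mat = expr.values.to_numpy(dtype=float)
    gene_names = expr.genes.to_numpy(dtype=object)
    in_set = np.asarray(expr.genes.isin(present))
    n_genes, n_samples = mat.shape
    m = in_set.sum()
    if n_genes == m:
        raise ValueError("gene set covers the whole matrix; no out-of-set genes")

    ranks = np.arange(n_genes, 0, -1, dtype=float)  # rank N at the top position
    scores = np.empty(n_samples)
    for j in range(n_samples):
        order = _ranked_order(mat[:, j], gene_names)
        hit = in_set[order]
        w = np.where(hit, ranks ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~hit) / (n_genes - m)
        scores[j] = np.sum(p_in - p_out)
    return ScoreVector(
        name=gene_set.name,
        scores=pd.Series(scores, index=expr.samples),
        normalization_tag="raw",
        coverage=coverage,
    )


def score_signatures(
    expr: ExpressionMatrix,
    sets: Sequence[GeneSet],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, ScoreVector]:
    """ssGSEA scores for several signatures on one (log-scale) matrix."""
    return {s.name: ssgsea_score(expr, s, alpha=alpha) for s in sets}


# ---------------------------------------------------------------------------
# normalisation of score vectors
# ---------------------------------------------------------------------------

def rescale_scores(scores: ScoreVector, method: str = "minmax_eps") -> ScoreVector:
    """Map cohort scores onto a positive range so log-ratios are defined.

    ``minmax_eps`` maps the cohort min/max affinely onto [0.01, 1];
    ``none`` is the identity (tag updated only).
    """
    if method == "none":
        return replace(scores, normalization_tag="rescaled")
    if method != "minmax_eps":
        raise ValueError(f"unknown rescale method {method!r}")
    x = scores.scores
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError(f"cannot min-max rescale constant scores for {scores.name!r}")
    y = RESCALE_EPS + (x - lo) / (hi - lo) * (1.0 - RESCALE_EPS)
    return replace(scores, scores=y, normalization_tag="rescaled")


def zscore(scores: ScoreVector) -> ScoreVector:
    """Standardise with the sample (n-1) standard deviation."""
    x = scores.scores
    if len(x) < 2:
        raise ValueError("z-scoring requires >= 2 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"constant scores for {scores.name!r}; z-score undefined")
    return replace(scores, scores=(x - x.mean()) / sd, normalization_tag="zscore")


def write_scores(scores: Iterable[ScoreVector], path: str | Path) -> None:
    """Long-format TSV: sample, signature, score, normalization_tag."""
    rows = []
    for sv in scores:
        for sample, value in sv.scores.items():
            rows.append((sample, sv.name, value, sv.normalization_tag))
    pd.DataFrame(rows, columns=["sample", "signature", "score", "normalization_tag"]).to_csv(
        path, sep="\t", index=False
    )


def read_scores(path: str | Path) -> dict[str, ScoreVector]:
    """Inverse of :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, ScoreVector] = {}
    for name, grp in df.groupby("signature", sort=False):
        tags = grp["normalization_tag"].unique()
        if len(tags) != 1:
            raise ValueError(f"signature {name!r} has mixed normalization tags")
        out[name] = ScoreVector(
            name=name,
            scores=pd.Series(grp["score"].to_numpy(), index=grp["sample"].to_numpy()),
            normalization_tag=tags[0],
        )
    return out
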
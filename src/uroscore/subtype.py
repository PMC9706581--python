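"""Luminal/basal subtype axis and sample-level subtype calls.

The BASE47 panel splits into a luminal half and a basal half.  Each half
is scored per sample by ssGSEA, rescaled onto a positive range, and the
natural log of the basal/luminal ratio defines the cohort's subtype
axis: positive values are basal-leaning, negative luminal-leaning.

Subtype calls come from average-linkage hierarchical clustering of the
BASE47 sub-matrix (distance 1 - Pearson between samples, genes z-scored
first), cut into two groups; the group with the higher mean basal score
is labelled "basal".  A three-way scheme overlays clinical stage:
non-muscle-invasive (NMI) samples are labelled NMI regardless of
cluster, muscle-invasive (MI) samples keep their cluster label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .signatures import (
    ExpressionMatrix,
    GeneSet,
    rescale_scores,
    ssgsea_score,
)

#: log base for the basal/luminal ratio: natural log
LOG_RATIO_BASE = float(np.e)


@dataclass
class SubtypeAxis:
    """Per-sample basal score, luminal score and log(basal/luminal)."""

    basal: pd.Series
    luminal: pd.Series
    log_ratio: pd.Series

    def __post_init__(self) -> None:
        if (self.basal <= 0).any() or (self.luminal <= 0).any():
            raise ValueError("basal and luminal scores must be positive before the ratio")
        if not np.isfinite(self.log_ratio).all():
            raise ValueError("non-finite log(basal/luminal) values")


@dataclass
class SubtypeCall:
    """Per-sample label in {NMI, luminal, basal} plus the method used."""

    labels: pd.Series
    method_tag: str

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"NMI", "luminal", "basal"}
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")


def subtype_axis(
    expr: ExpressionMatrix,
    base47_luminal: GeneSet,
    base47_basal: GeneSet,
    alpha: float = 0.25,
) -> SubtypeAxis:
    """Score both BASE47 halves, rescale to positive, take the log ratio."""
    b = rescale_scores(ssgsea_score(expr, base47_basal, alpha=alpha), "minmax_eps")
    l = rescale_scores(ssgsea_score(expr, base47_luminal, alpha=alpha), "minmax_eps")
    r = np.log(b.scores / l.scores)
    return SubtypeAxis(basal=b.scores, luminal=l.scores, log_ratio=r)


def cluster_subtypes(
    expr: ExpressionMatrix,
    base47_luminal: GeneSet,
    base47_basal: GeneSet,
    k: int = 2,
    linkage_method: str = "average",
    alpha: float = 0.25,
) -> SubtypeCall:
    """Two-group hierarchical clustering of samples on the BASE47 panel.

    Genes are z-scored across samples, sample-sample distance is
    1 - Pearson correlation, linkage is average by default.  The cluster
    with the higher mean basal ssGSEA score is named "basal".
    """
    if k != 2:
        raise ValueError("subtype clustering is defined for k = 2 (luminal vs basal)")
    n = expr.values.shape[1]
    if n < k:
        raise ValueError(f"need >= {k} samples, got {n}")
    panel = [g for g in (*base47_luminal.genes, *base47_basal.genes) if g in expr.genes]
    if len(panel) < 2:
        raise ValueError("fewer than 2 BASE47 genes present in the matrix")
    sub = expr.values.loc[panel]
    sd = sub.std(axis=1, ddof=1)
    sub = sub.loc[sd > 0]
    if sub.shape[0] < 2:
        raise ValueError("BASE47 sub-matrix is constant; cannot cluster")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    dist = pdist(z.to_numpy().T, metric="correlation")
    # correlation distance can dip microscopically below 0 from rounding
    dist = np.clip(dist, 0.0, None)
    groups = fcluster(linkage(dist, method=linkage_method), t=k, criterion="maxclust")
    groups = pd.Series(groups, index=expr.samples)

    basal_scores = ssgsea_score(expr, base47_basal, alpha=alpha).scores
    means = basal_scores.groupby(groups).mean()
    basal_group = means.idxmax()
    labels = groups.map(lambda g: "basal" if g == basal_group else "luminal")
    return SubtypeCall(labels=labels, method_tag="clinical+clustering")


def assign_three_way(calls: SubtypeCall, stage: Mapping[str, str] | pd.Series) -> SubtypeCall:
    """Overlay clinical stage: NMI samples -> NMI, MI keep their cluster label."""
    stage = pd.Series(stage)
    missing = [s for s in calls.labels.index if s not in stage.index]
    if missing:
        raise ValueError(f"missing stage annotation for samples: {missing}")
    bad = set(stage.loc[calls.labels.index].unique()) - {"NMI", "MI"}
    if bad:
        raise ValueError(f"stage annotation must be NMI or MI, got {sorted(bad)}")
    labels = calls.labels.copy()
    labels[stage.loc[labels.index] == "NMI"] = "NMI"
    return SubtypeCall(labels=labels, method_tag=calls.method_tag)


def nearest_centroid_assign(
    expr: ExpressionMatrix,
    reference: ExpressionMatrix,
    reference_labels: pd.Series,
    base47_luminal: GeneSet,
    base47_basal: GeneSet,
) -> SubtypeCall:
    """Assign subtypes by highest Pearson correlation to reference centroids.

    Fallback for cohorts without clinical stage: centroids are the mean
    BASE47 profiles of labelled reference samples (labels may include
    NMI), and each query sample takes the label of the closest centroid.
    """
    panel = [
        g for g in (*base47_luminal.genes, *base47_basal.genes)
        if g in expr.genes and g in reference.genes
    ]
    if len(panel) < 2:
        raise ValueError("fewer than 2 shared BASE47 genes between query and reference")
    missing = [s for s in reference.samples if s not in reference_labels.index]
    if missing:
        raise ValueError(f"missing labels for reference samples: {missing}")
    ref = reference.values.loc[panel]
    centroids = ref.T.groupby(reference_labels.loc[ref.columns]).mean().T
    query = expr.values.loc[panel]
    corr = pd.DataFrame(
        np.corrcoef(query.T, centroids.T)[: query.shape[1], query.shape[1]:],
        index=expr.samples,
        columns=centroids.columns,
    )
    return SubtypeCall(labels=corr.idxmax(axis=1), method_tag="nearest_centroid")


def write_calls(calls: SubtypeCall, path: str | Path) -> None:
    df = pd.DataFrame({
        "sample": calls.labels.index,
        "label": calls.labels.to_numpy(),
        "method_tag": calls.method_tag,
    })
    df.to_csv(path, sep="\t", index=False)
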
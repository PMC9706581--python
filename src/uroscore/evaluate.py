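"""Evaluation of response prediction: ROC/AUC, quartile stratification,
and the 2x2 Fisher exact test linking score quartiles to response.

AUC uses the Mann-Whitney concordance convention: ties between a
responder and a non-responder score count 0.5, which equals the
trapezoidal area under the empirical ROC curve stored alongside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class QuartileStrata:
    """Per-sample quartile label; Q1 lowest scores, Q4 highest."""

    labels: pd.Series
    boundaries: tuple[float, float, float]


def roc_auc(scores: pd.Series, labels: pd.Series) -> ROCResult:
    """ROC curve at every distinct score threshold plus the trapezoidal AUC."""
    y = labels.reindex(scores.index).to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = metrics.roc_curve(
        y, scores.to_numpy(dtype=float), drop_intermediate=False
    )
    auc = metrics.auc(fpr, tpr)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc),
                     n_pos=n_pos, n_neg=n_neg)


def quartile_stratify(scores: pd.Series) -> QuartileStrata:
    """Quartile labels at the empirical 25/50/75 percentiles.

    A score tied with a boundary goes to the lower quartile, so the
    Q1-vs-Q4 contrast is deterministic.
    """
    n = len(scores)
    if n < 4:
        raise ValueError(f"quartile stratification needs >= 4 samples, got {n}")
    x = scores.to_numpy(dtype=float)
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    if q25 == q75:
        raise ValueError("degenerate strata: 25th and 75th percentiles coincide")
    labels = np.select(
        [x <= q25, x <= q50, x <= q75],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    return QuartileStrata(
        labels=pd.Series(labels, index=scores.index),
        boundaries=(float(q25), float(q50), float(q75)),
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact p (probability ordering) and the sample
    odds ratio, Haldane-corrected (+0.5 per cell) when any cell is zero.

    Returns ``(p, odds_ratio)``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValueError("at least one nonzero margin required")
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b = t[0]
    c, d = t[1]
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    return float(res.pvalue), float(odds)


def quartile_response_table(strata: QuartileStrata, responder: pd.Series,
                            low: str = "Q1", high: str = "Q4") -> np.ndarray:
    """2x2 responders/non-responders count table for two quartiles."""
    y = responder.reindex(strata.labels.index)
    rows = []
    for q in (low, high):
        mask = strata.labels == q
        rows.append([int(y[mask].sum()), int((1 - y[mask]).sum())])
    return np.array(rows)


def compare_scores(scores: dict[str, pd.Series], labels: pd.Series) -> pd.DataFrame:
    """Side-by-side AUCs for several scores (e.g. the piecewise ICI
    response score, the raw Macro-C3 score, and an externally supplied
    comparator such as TIDE) against the same response labels."""
    rows = []
    for name, s in scores.items():
        res = roc_auc(s, labels)
        rows.append((name, res.auc, res.n_pos, res.n_neg))
    return pd.DataFrame(rows, columns=["score", "auc", "n_pos", "n_neg"])


def write_roc(res: ROCResult, out_dir: str | Path, name: str = "roc") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "threshold": res.thresholds,
        "fpr": res.fpr,
        "tpr": res.tpr,
    }).to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    with open(out_dir / f"{name}.json", "w") as fh:
        json.dump({"auc": res.auc, "n_pos": res.n_pos, "n_neg": res.n_neg}, fh, indent=2)
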
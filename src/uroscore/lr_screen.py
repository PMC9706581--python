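"""Ligand-receptor interaction screening between cell clusters.

The interaction strength of a ligand-receptor pair from a sender to a
receiver cluster is the arithmetic mean of (i) the mean log-normalised
ligand expression over sender cells and (ii) the mean log-normalised
receptor expression over receiver cells.  A pair is only scored when
the ligand is expressed (count > 0) in more than ``min_frac`` (10% by
default) of sender cells and the receptor in more than ``min_frac`` of
receiver cells; otherwise it is gated out and carries no p value.

Significance is empirical: cluster labels are reshuffled over all cells
``n_perm`` times (1,000 by default) and the add-one-corrected p value
is (1 + #{permuted strength >= observed}) / (n_perm + 1).  An
exhaustive mode enumerates every distinct label assignment instead,
which is feasible for very small bundles and serves as ground truth.

The interaction-vs-exhaustion screen correlates per-sample interaction
strengths with the per-sample fraction of exhausted CD8+ T cells and
classifies each pair as a significant positive, significant negative,
or non-significant correlate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sc_rules import SingleCellBundle

#: expression gate: fraction of cluster cells that must express the gene
MIN_EXPR_FRAC = 0.10
#: default number of label permutations
N_PERM = 1000
#: per-cell library-size normalisation target before log1p
NORM_TARGET = 1e4


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor gene symbols must be nonempty")
        if not self.name:
            object.__setattr__(self, "name", f"{self.ligand}_{self.receptor}")


@dataclass
class InteractionResult:
    pair: LRPair
    sender: str
    receiver: str
    strength: float | None
    p_value: float | None
    gated: bool


def read_lr_panel(path: str | Path) -> list[LRPair]:
    """Two-column TSV (ligand, receptor) -> LR panel with unique names."""
    df = pd.read_csv(path, sep="\t")
    pairs = [LRPair(row.iloc[0], row.iloc[1]) for _, row in df.iterrows()]
    names = [p.name for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate pair names in LR panel")
    return pairs


def log_normalized_expression(bundle: SingleCellBundle) -> np.ndarray:
    """Per-cell library-size normalisation to ``NORM_TARGET`` then log1p."""
    counts = bundle.counts.astype(float)
    lib = np.asarray(counts.sum(axis=0)).ravel()
    scale = NORM_TARGET / np.maximum(lib, 1.0)
    mat = counts.multiply(scale[None, :]).toarray()
    return np.log1p(mat)


def _gene_row(bundle: SingleCellBundle, gene: str) -> int:
    idx = bundle.genes.get_indexer([gene])
    if idx[0] < 0:
        raise ValueError(f"gene {gene!r} not in the matrix")
    return int(idx[0])


def _strength(lig_expr: np.ndarray, rec_expr: np.ndarray,
              sender_mask: np.ndarray, receiver_mask: np.ndarray) -> float:
    return 0.5 * (lig_expr[sender_mask].mean() + rec_expr[receiver_mask].mean())


def interaction_strength(
    bundle: SingleCellBundle,
    pair: LRPair,
    sender: str,
    receiver: str,
    min_frac: float = MIN_EXPR_FRAC,
    _log_expr: np.ndarray | None = None,
) -> InteractionResult:
    """Strength of one pair between two clusters, or a gated result."""
    clusters = bundle.cell_cluster.loc[bundle.cells].to_numpy()
    for name in (sender, receiver):
        if name not in clusters:
            raise ValueError(f"unknown cluster {name!r}")
    li = _gene_row(bundle, pair.ligand)
    ri = _gene_row(bundle, pair.receptor)
    s_mask = clusters == sender
    r_mask = clusters == receiver
    lig_counts = bundle.counts[li].toarray().ravel()
    rec_counts = bundle.counts[ri].toarray().ravel()
    lig_frac = (lig_counts[s_mask] > 0).mean()
    rec_frac = (rec_counts[r_mask] > 0).mean()
    if lig_frac <= min_frac or rec_frac <= min_frac:
        return InteractionResult(pair, sender, receiver,
                                 strength=None, p_value=None, gated=True)
    log_expr = log_normalized_expression(bundle) if _log_expr is None else _log_expr
    strength = _strength(log_expr[li], log_expr[ri], s_mask, r_mask)
    return InteractionResult(pair, sender, receiver,
                             strength=float(strength), p_value=None, gated=False)


def _distinct_binary_assignments(n_cells: int, n_sender: int):
    """All distinct ways to choose which cells form the sender cluster
    (the rest form the receiver cluster); only valid for 2 clusters."""
    for sender_cells in combinations(range(n_cells), n_sender):
        mask = np.zeros(n_cells, bool)
        mask[list(sender_cells)] = True
        yield mask


def permutation_test(
    bundle: SingleCellBundle,
    pair: LRPair,
    sender: str,
    receiver: str,
    n_perm: int = N_PERM,
    seed: int = 0,
    min_frac: float = MIN_EXPR_FRAC,
    exhaustive: bool = False,
    stratify_by_sample: bool = False,
) -> InteractionResult:
    """Empirical p value by reshuffling cluster labels over all cells.

    With ``stratify_by_sample=True`` labels are shuffled within each
    sample instead of jointly (the jointly shuffled default matches the
    usual convention).  With ``exhaustive=True`` (2-cluster bundles
    only) every distinct assignment of cells to the two clusters is
    enumerated and p = #{strength >= observed} / #assignments.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    base = interaction_strength(bundle, pair, sender, receiver, min_frac=min_frac)
    if base.gated:
        raise ValueError("pair is gated by the expression-fraction rule; no test")
    observed = base.strength
    log_expr = log_normalized_expression(bundle)
    li = _gene_row(bundle, pair.ligand)
    ri = _gene_row(bundle, pair.receptor)
    clusters = bundle.cell_cluster.loc[bundle.cells].to_numpy()
    lig, rec = log_expr[li], log_expr[ri]

    if exhaustive:
        uniq = np.unique(clusters)
        if len(uniq) != 2 or {sender, receiver} != set(uniq):
            raise ValueError("exhaustive enumeration supports exactly 2 clusters")
        n_sender = int((clusters == sender).sum())
        stats_all = [
            _strength(lig, rec, mask, ~mask)
            for mask in _distinct_binary_assignments(len(clusters), n_sender)
        ]
        stats_all = np.asarray(stats_all)
        p = float((stats_all >= observed - 1e-12).mean())
        return InteractionResult(pair, sender, receiver, strength=observed,
                                 p_value=p, gated=False)

    rng = np.random.default_rng(seed)
    samples = bundle.cell_sample.loc[bundle.cells].to_numpy()
    sample_groups = [np.flatnonzero(samples == s) for s in np.unique(samples)]
    count = 0
    for _ in range(n_perm):
        if stratify_by_sample:
            perm = clusters.copy()
            for idx in sample_groups:
                perm[idx] = perm[rng.permutation(idx)]
        else:
            perm = rng.permutation(clusters)
        s = _strength(lig, rec, perm == sender, perm == receiver)
        if s >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return InteractionResult(pair, sender, receiver, strength=observed,
                             p_value=float(p), gated=False)


def screen_pairs(
    bundle: SingleCellBundle,
    pairs: Sequence[LRPair],
    sender: str,
    receiver: str,
    n_perm: int = N_PERM,
    seed: int = 0,
    min_frac: float = MIN_EXPR_FRAC,
) -> pd.DataFrame:
    """Strength + permutation p for a whole panel between two clusters."""
    rows = []
    for i, pair in enumerate(pairs):
        res = interaction_strength(bundle, pair, sender, receiver, min_frac=min_frac)
        if not res.gated:
            res = permutation_test(bundle, pair, sender, receiver,
                                   n_perm=n_perm, seed=seed + i, min_frac=min_frac)
        rows.append({
            "pair": pair.name, "sender": sender, "receiver": receiver,
            "strength": res.strength, "p_value": res.p_value, "gated": res.gated,
        })
    return pd.DataFrame(rows)


def interaction_exhaustion_screen(
    strengths: pd.DataFrame,
    exhausted_fraction: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate per-sample interaction strengths with the per-sample
    exhausted CD8+ T-cell fraction.

    ``strengths`` is pairs x samples.  Pairs with a constant strength
    vector are skipped (flagged); the rest get a Pearson r, a two-sided
    t-distribution p, and a sign class in {positive, negative, ns}.
    """
    common = [s for s in strengths.columns if s in exhausted_fraction.index]
    if len(common) < 3:
        raise ValueError("need >= 3 samples with both quantities")
    y = exhausted_fraction.loc[common].to_numpy(dtype=float)
    rows = []
    for pair, row in strengths[common].iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"pair": pair, "r": np.nan, "p_value": np.nan,
                         "sign_class": "skipped"})
            continue
        r, p = stats.pearsonr(x, y)
        if p < alpha:
            cls = "positive" if r > 0 else "negative"
        else:
            cls = "ns"
        rows.append({"pair": pair, "r": float(r), "p_value": float(p),
                     "sign_class": cls})
    return pd.DataFrame(rows).set_index("pair")


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p values (optional, off by default)."""
    p = p.dropna()
    n = len(p)
    order = p.sort_values().index
    ranked = p.loc[order].to_numpy() * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    return pd.Series(np.clip(adj, 0, 1), index=order).reindex(p.index)
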
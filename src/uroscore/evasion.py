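"""The immune-evasion model: two regression lines, their intersection
threshold, the piecewise ICI response score, and the responder-fraction
curve over a grid of log(basal/luminal) cutoffs.

The model regresses the z-scored cytotoxicity score Z(C) and the
z-scored Macro-C3 score Z(M) on the log(basal/luminal) axis by ordinary
least squares, giving lines L_C and L_M.  Their intersection (a, b)
splits the cohort: below the threshold a, T-cell cytotoxicity dominates
and the Macro-C3 score tracks response to PD-L1 blockade, so the score
itself is the ICI response score; at or above a, the Macro-C3 score
reflects immune-evasion capacity instead, and those samples receive the
cohort-minimum Macro-C3 score (predicted least likely to respond).

A useful identity: when both responses are exactly z-scored, each OLS
line passes through (mean(r), 0), so the intersection is pinned at
a = mean(log-ratio), b = 0.  The fit is implemented generically (any
pair of response vectors), and this identity serves as a cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import ScoreVector

#: number of evenly distributed log(basal/luminal) cutoff points
N_CUTOFFS = 256
#: slopes closer than this are treated as parallel (no intersection)
PARALLEL_TOL = 1e-12


@dataclass
class EvasionModelFit:
    slope_c: float
    intercept_c: float
    slope_m: float
    intercept_m: float
    a: float  # log-ratio threshold (x of the intersection)
    b: float  # z-score at the intersection
    n_samples: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "EvasionModelFit":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ICIPrediction:
    """Per-sample piecewise ICI response score.

    ``rule_tag`` is "below:macro_score" for samples with log-ratio < a
    and "above:cohort_min" otherwise.
    """

    scores: pd.Series
    threshold_a: float
    rule_tag: pd.Series


@dataclass
class CutoffGrid:
    """Responder fraction below each of the evenly spaced cutoffs.

    ``fraction`` is NaN where no sample falls at or below the cutoff
    (flagged undefined); ``n_below`` carries the denominator.
    """

    cutoffs: np.ndarray
    fraction: np.ndarray
    n_below: np.ndarray


def _aligned(series: pd.Series, other: pd.Series, what: str) -> None:
    if not series.index.equals(other.index):
        if set(series.index) == set(other.index):
            return  # same samples, different order: caller reindexes
        raise ValueError(f"sample sets of {what} do not match")


def fit_evasion_model(
    log_ratio: pd.Series,
    cytotox_z: ScoreVector | pd.Series,
    macro_z: ScoreVector | pd.Series,
) -> EvasionModelFit:
    """OLS of each z-scored signature on the log-ratio; intersect the lines.

    a = (intercept_M - intercept_C) / (slope_C - slope_M),
    b = slope_C * a + intercept_C.
    """
    c = cytotox_z.scores if isinstance(cytotox_z, ScoreVector) else cytotox_z
    m = macro_z.scores if isinstance(macro_z, ScoreVector) else macro_z
    _aligned(log_ratio, c, "log_ratio and cytotoxicity")
    _aligned(log_ratio, m, "log_ratio and Macro-C3")
    c = c.reindex(log_ratio.index)
    m = m.reindex(log_ratio.index)
    n = len(log_ratio)
    if n < 3:
        raise ValueError(f"need >= 3 samples to fit the evasion model, got {n}")
    x = log_ratio.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("log(basal/luminal) is constant; regression undefined")
    fit_c = stats.linregress(x, c.to_numpy(dtype=float))
    fit_m = stats.linregress(x, m.to_numpy(dtype=float))
    dslope = fit_c.slope - fit_m.slope
    if abs(dslope) < PARALLEL_TOL:
        raise ValueError("the two regression lines are parallel; no intersection")
    a = (fit_m.intercept - fit_c.intercept) / dslope
    b = fit_c.slope * a + fit_c.intercept
    return EvasionModelFit(
        slope_c=float(fit_c.slope),
        intercept_c=float(fit_c.intercept),
        slope_m=float(fit_m.slope),
        intercept_m=float(fit_m.intercept),
        a=float(a),
        b=float(b),
        n_samples=n,
    )


def ici_response_score(
    macro: ScoreVector | pd.Series,
    log_ratio: pd.Series,
    threshold_a: float,
) -> ICIPrediction:
    """Piecewise score: Macro-C3 below the threshold, cohort minimum above.

    The minimum is taken over the WHOLE cohort (below-threshold samples
    included), so every at-or-above-threshold sample is floored to the
    least response-prone score seen anywhere.
    """
    m = macro.scores if isinstance(macro, ScoreVector) else macro
    if len(m) == 0:
        raise ValueError("empty cohort")
    _aligned(log_ratio, m, "log_ratio and Macro-C3")
    m = m.reindex(log_ratio.index)
    below = log_ratio < threshold_a
    scores = m.where(below, other=m.min())
    rule = pd.Series(
        np.where(below, "below:macro_score", "above:cohort_min"),
        index=log_ratio.index,
    )
    return ICIPrediction(scores=scores, threshold_a=float(threshold_a), rule_tag=rule)


def responder_fraction_curve(
    log_ratio: pd.Series,
    responder: pd.Series,
    n_points: int = N_CUTOFFS,
    window_frac: float | None = None,
) -> CutoffGrid:
    """Fraction of responders among samples at or below each cutoff.

    ``n_points`` cutoffs are evenly spaced from min to max of the
    log-ratio; at the last cutoff the fraction equals the cohort's
    overall responder rate.  With ``window_frac`` set (e.g. 0.2), a
    sliding-window variant is computed instead: the fraction among
    samples within ``window_frac * range / 2`` of each cutoff.
    """
    if len(log_ratio) < 1:
        raise ValueError("need >= 1 sample")
    _aligned(log_ratio, responder, "log_ratio and responder labels")
    y = responder.reindex(log_ratio.index).to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValueError("responder labels must be binary 0/1")
    r = log_ratio.to_numpy(dtype=float)
    cutoffs = np.linspace(r.min(), r.max(), n_points)
    if window_frac is None:
        in_window = r[None, :] <= cutoffs[:, None]
    else:
        half = window_frac * np.ptp(r) / 2.0
        in_window = np.abs(r[None, :] - cutoffs[:, None]) <= half
    n_below = in_window.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_below > 0, in_window @ y / np.maximum(n_below, 1), np.nan)
    return CutoffGrid(cutoffs=cutoffs, fraction=frac, n_below=n_below)


def bootstrap_threshold_ci(
    log_ratio: pd.Series,
    cytotox_z: pd.Series,
    macro_z: pd.Series,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the threshold a (utility only).

    Samples are resampled with replacement and the two lines refitted;
    resamples with a constant log-ratio or parallel lines are skipped.
    """
    rng = np.random.default_rng(seed)
    n = len(log_ratio)
    draws: list[float] = []
    while len(draws) < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            fit = fit_evasion_model(
                log_ratio.iloc[idx].reset_index(drop=True),
                cytotox_z.iloc[idx].reset_index(drop=True),
                macro_z.iloc[idx].reset_index(drop=True),
            )
        except ValueError:
            continue
        draws.append(fit.a)
    lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def write_prediction(pred: ICIPrediction, path: str | Path) -> None:
    pd.DataFrame({
        "sample": pred.scores.index,
        "ici_response_score": pred.scores.to_numpy(),
        "rule_tag": pred.rule_tag.to_numpy(),
        "threshold_a": pred.threshold_a,
    }).to_csv(path, sep="\t", index=False)


def write_curve(grid: CutoffGrid, path: str | Path) -> None:
    pd.DataFrame({
        "cutoff": grid.cutoffs,
        "responder_fraction": grid.fraction,
        "n_below": grid.n_below,
    }).to_csv(path, sep="\t", index=False)
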
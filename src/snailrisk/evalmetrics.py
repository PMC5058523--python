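"""Threshold-free and threshold-based evaluation of suitability scores.

Presence-background models are scored against background cells standing in
for absences: AUC is the rank (Mann-Whitney) statistic with ties counted
one half; TSS = sensitivity + specificity - 1 under the prediction rule
"present when score >= threshold". The operational threshold is the one
maximizing sensitivity + specificity (MTSS), the same rule used to
binarize suitability maps before any overlap arithmetic. Above MTSS the
continuous map is split into three equal-width classes (poor / medium /
highly suitable); below it is unsuitable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .raster import Grid

__all__ = [
    "ThresholdSearch",
    "auc",
    "mtss_threshold",
    "tss_at",
    "binarize",
    "categorize",
    "CATEGORY_LABELS",
]

CATEGORY_LABELS = {0: "unsuitable", 1: "poor", 2: "medium",
                   3: "highly suitable"}


@dataclass
class ThresholdSearch:
    """Full sensitivity/specificity profile over candidate thresholds."""

    table: pd.DataFrame  # columns: threshold, sensitivity, specificity, tss
    mtss_threshold: float

    @property
    def best(self) -> pd.Series:
        return self.table.loc[
            self.table["threshold"] == self.mtss_threshold].iloc[0]


def _check_scores(pos_scores, neg_scores) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    return pos, neg


def auc(pos_scores, neg_scores) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2."""
    pos, neg = _check_scores(pos_scores, neg_scores)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def tss_at(pos_scores, neg_scores, threshold: float) -> float:
    """True skill statistic at a threshold (present when score >= threshold)."""
    pos, neg = _check_scores(pos_scores, neg_scores)
    sens = float(np.mean(pos >= threshold))
    spec = float(np.mean(neg < threshold))
    return sens + spec - 1.0


def mtss_threshold(pos_scores, neg_scores) -> ThresholdSearch:
    """Search all unique scores for the sensitivity+specificity maximizer.

    Ties resolve toward the smallest threshold, the more inclusive (larger
    suitable area) and hence more conservative choice for risk screening.
    """
    pos, neg = _check_scores(pos_scores, neg_scores)
    cand = np.unique(np.concatenate([pos, neg]))
    sens = np.array([np.mean(pos >= t) for t in cand])
    spec = np.array([np.mean(neg < t) for t in cand])
    tss = sens + spec - 1.0
    best = int(np.flatnonzero(tss == tss.max())[0])  # smallest candidate
    table = pd.DataFrame({"threshold": cand, "sensitivity": sens,
                          "specificity": spec, "tss": tss})
    return ThresholdSearch(table=table, mtss_threshold=float(cand[best]))


def binarize(suitability: Grid, threshold: float) -> Grid:
    """Presence-absence map: 1 where value >= threshold; nodata preserved."""
    v = suitability.values
    out = np.where(v >= threshold, 1.0, 0.0)
    out[~suitability.mask] = np.nan
    return suitability.with_values(out)


def categorize(suitability: Grid, mtss: float) -> Grid:
    """Four-class suitability map keyed on the MTSS threshold.

    Class 0 (unsuitable) below ``mtss``; the interval [mtss, 1] is split
    into three equal-width classes: 1 poor, 2 medium, 3 highly suitable.
    The value 1.0 falls in class 3.
    """
    if not 0.0 < mtss < 1.0:
        raise ValueError("mtss must lie strictly inside (0, 1)")
    v = suitability.values
    width = (1.0 - mtss) / 3.0
    with np.errstate(invalid="ignore"):
        cls = np.where(v < mtss, 0.0,
                       np.minimum(3.0, np.floor((v - mtss) / width) + 1.0))
    cls[~suitability.mask] = np.nan
    return suitability.with_values(cls)
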
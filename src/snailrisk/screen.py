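"""Collinearity screening of predictor layers.

Multicollinear predictors destabilise variable-importance diagnostics, so
before fitting, pairwise Pearson correlations are computed over a common
random sample of data cells and one member of every pair with |r| above a
threshold (default 0.7, i.e. r^2 > 0.49) is removed. Which member survives
is decided by a user-supplied priority ordering standing in for expert
judgment of biological relevance — e.g. keeping soil pH over total
exchangeable bases because pH directly affects shell formation in
mollusks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import GridStack

__all__ = ["ScreenResult", "corr_matrix", "prune_correlated"]


@dataclass
class ScreenResult:
    """Outcome of a collinearity screen.

    ``retained`` preserves priority order; ``dropped`` records, for each
    removed layer, the retained partner it exceeded the threshold with and
    the offending correlation.
    """

    corr: pd.DataFrame
    retained: list[str]
    dropped: list[tuple[str, str, float]]
    threshold: float

    def report(self) -> pd.DataFrame:
        rows = [{"layer": n, "status": "retained", "partner": "", "r": np.nan}
                for n in self.retained]
        rows += [{"layer": n, "status": "dropped", "partner": p, "r": r}
                 for n, p, r in self.dropped]
        return pd.DataFrame(rows)


def corr_matrix(stack: GridStack, sample_n: int = 10_000,
                seed: int = 0) -> pd.DataFrame:
    """Pearson correlations over a common random sample of data cells.

    A zero-variance layer has undefined correlations; these are flagged
    with a warning and treated as 0 so screening can proceed.
    """
    cells = stack.data_cells()
    if cells.size < 3:
        raise ValueError("need at least 3 data cells for correlations")
    if sample_n < cells.size:
        rng = np.random.default_rng(seed)
        cells = rng.choice(cells, size=sample_n, replace=False, shuffle=False)
    x = stack.matrix(cells)
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [n for n, d in zip(stack.names, degenerate) if d]
        warnings.warn(
            f"zero-variance layer(s) in correlation sample: {bad};"
            " their correlations are treated as 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=stack.names, columns=stack.names)


def prune_correlated(corr: pd.DataFrame, threshold: float = 0.7,
                     priority: list[str] | None = None) -> ScreenResult:
    """Greedily remove one member of every over-correlated pair.

    Pairs are visited in descending |r|; while any retained pair exceeds
    the (strict) threshold, the lower-priority member is dropped. Ties in
    |r| break by priority rank, then lexicographic name, so the result is
    deterministic. Priority defaults to the input column order (earlier =
    higher priority).
    """
    names = list(corr.columns)
    if priority is None:
        priority = names
    if set(priority) != set(names):
        raise ValueError("priority must cover exactly the correlated layers")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    rank = {n: i for i, n in enumerate(priority)}
    r = corr.to_numpy()

    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(r[i, j]) > threshold:
                a, b = names[i], names[j]
                tie = tuple(sorted((rank[a], rank[b])))
                pairs.append((-abs(r[i, j]), tie, a, b))
    pairs.sort()

    retained = set(names)
    dropped: list[tuple[str, str, float]] = []
    for negr, _, a, b in pairs:
        if a in retained and b in retained:
            loser, keeper = (a, b) if rank[a] > rank[b] else (b, a)
            retained.discard(loser)
            dropped.append((loser, keeper, -negr))
    retained_ordered = [n for n in priority if n in retained]
    return ScreenResult(corr=corr, retained=retained_ordered,
                        dropped=dropped, threshold=threshold)
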
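"""Habitat overlap statistics and the three-component invasion-risk score.

The invasion-risk model asks where a forest snail is most likely to invade
crop plantations. It combines, per crop-suitable cell: (1) the snail's
climatic suitability there (its categorical suitability map rescaled to
[0, 1]), (2) a land-cover transformation term (1 on intact forest, 0 on
transformed or degraded land), and (3) proximity to existing snail
records (rescaled inverse Euclidean distance, closest = 1). The three
terms are added without weights and the sum rescaled to [0, 1]; 0 reads
as low and 1 as high invasion risk.

Overlap statistics compare the two species' presence-absence maps:
cellwise intersection, and the proportional overlap |A ∧ B| / min(|A|,
|B|) — shared suitable pixels over the suitable-pixel count of the
smaller map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Grid, latitude_band_counts, rescale01

__all__ = [
    "RiskComponents",
    "overlap_map",
    "proportional_overlap",
    "landcover_component",
    "invasion_risk",
    "risk_by_latitude",
    "future_risk_series",
]


def _binary(g: Grid) -> np.ndarray:
    return g.mask & (g.values == 1)


def overlap_map(a: Grid, b: Grid) -> Grid:
    """Cellwise AND of two presence-absence maps; nodata where either is."""
    a.require_alignment(b)
    both = np.where(_binary(a) & _binary(b), 1.0, 0.0)
    both[~(a.mask & b.mask)] = np.nan
    return a.with_values(both)


def proportional_overlap(a: Grid, b: Grid) -> float:
    """Shared suitable pixels over the smaller map's suitable-pixel count."""
    a.require_alignment(b)
    na, nb = int(_binary(a).sum()), int(_binary(b).sum())
    if na == 0 and nb == 0:
        raise ValueError("proportional overlap is undefined for two empty maps")
    inter = int((_binary(a) & _binary(b)).sum())
    denom = min(n for n in (na, nb) if n > 0)  # smaller non-empty map
    return inter / denom


def landcover_component(landcover: Grid, forest_classes: set[float],
                        known_classes: set[float] | None = None) -> Grid:
    """Binary land-cover transformation map: 1 for forest classes, else 0.

    When ``known_classes`` declares the expected class universe, any map
    code outside ``forest_classes | known_classes`` triggers a warning and
    is mapped to 0 (treated as transformed/degraded land).
    """
    vals = landcover.values
    forest = set(float(c) for c in forest_classes)
    if known_classes is not None:
        seen = set(np.unique(vals[landcover.mask]).tolist())
        unseen = seen - forest - set(float(c) for c in known_classes)
        if unseen:
            warnings.warn(
                f"unrecognized land-cover class code(s) {sorted(unseen)}"
                " mapped to non-forest (0)", stacklevel=2)
    out = np.where(np.isin(vals, list(forest)), 1.0, 0.0)
    out[~landcover.mask] = np.nan
    return landcover.with_values(out)


@dataclass
class RiskComponents:
    """The three aligned component maps entering the risk sum.

    ``suitability`` is the snail's categorical (or continuous) suitability
    restricted to crop-suitable cells; ``landcover`` is binary; ``distance``
    the rescaled proximity map in [0, 1].
    """

    suitability: Grid
    landcover: Grid
    distance: Grid

    def __post_init__(self) -> None:
        self.suitability.require_alignment(self.landcover)
        self.suitability.require_alignment(self.distance)
        d = self.distance.values[self.distance.mask]
        if d.size and (d.min() < 0 or d.max() > 1):
            raise ValueError("distance component must lie within [0, 1]")


def invasion_risk(components: RiskComponents) -> Grid:
    """Unweighted sum of the three components, rescaled to [0, 1].

    The suitability component is itself rescaled to [0, 1] first (the
    categorical coding 0-3 otherwise dominates the binary and distance
    terms); cells where any component is nodata — in particular cells not
    suitable for the crop — stay nodata.
    """
    suit01 = rescale01(components.suitability)
    total = (suit01.values + components.landcover.values
             + components.distance.values)
    return rescale01(components.suitability.with_values(total))


def risk_by_latitude(risk: Grid, high_threshold: float = 0.5,
                     band_width: float = 1.0) -> pd.DataFrame:
    """Counts of high- and low-risk cells per latitude band."""
    hi = np.where(risk.mask, (risk.values >= high_threshold).astype(float),
                  np.nan)
    counts = latitude_band_counts(risk.with_values(hi), band_width)
    out = counts.pivot_table(index=["band_south", "band_north"],
                             columns="value", values="count",
                             fill_value=0, aggfunc="sum")
    out = out.rename(columns={0.0: "n_low", 1.0: "n_high"}).reset_index()
    for col in ("n_low", "n_high"):
        if col not in out:
            out[col] = 0
    out.columns.name = None
    return out[["band_south", "band_north", "n_high", "n_low"]]


def future_risk_series(snail_occupancy_series: list[Grid],
                       crop_suitability_series: list[Grid]) -> list[Grid]:
    """Per-period overlap of dispersal-constrained occupancy with crop area.

    Occupancy maps may be consensus frequencies in [0, 1] (the mean over
    stochastic replicates); the result per period is frequency x crop
    presence, rescaled to percent.
    """
    if len(snail_occupancy_series) != len(crop_suitability_series):
        raise ValueError("series lengths differ")
    out = []
    for occ, crop in zip(snail_occupancy_series, crop_suitability_series):
        occ.require_alignment(crop)
        v = 100.0 * occ.values * np.where(_binary(crop), 1.0, 0.0)
        v[~(occ.mask & crop.mask)] = np.nan
        out.append(occ.with_values(v))
    return out
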
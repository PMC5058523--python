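"""Demographic validation of predicted suitability categories.

Field sites with quadrat counts of adults and juveniles are assigned the
suitability category of the cell they fall in, and group means of a
demographic parameter (adults, juveniles, or juveniles per adult) are
compared between category groups with a Welch two-sample t-test — the
unequal-variance form, since sites per category are rarely balanced. If
the suitability model is ecologically meaningful, highly suitable sites
should carry denser populations than poor or unsuitable ones.

Juveniles-per-adult is undefined for adult-free quadrats; such records
are excluded from that parameter with an exclusion count rather than an
invented value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evalmetrics import categorize
from .raster import Grid

__all__ = ["SiteRecord", "assign_sites", "compare_groups"]

PARAMETERS = ("adults", "juveniles", "juveniles_per_adult")


@dataclass
class SiteRecord:
    """One field site with its predicted suitability and quadrat counts."""

    site_id: str
    lon: float
    lat: float
    suitability_value: float
    category: int
    adults: float
    juveniles: float

    @property
    def juveniles_per_adult(self) -> float | None:
        if self.adults > 0:
            return self.juveniles / self.adults
        return None


def assign_sites(sites: pd.DataFrame, suitability: Grid,
                 mtss: float) -> list[SiteRecord]:
    """Attach suitability value and category to each site.

    ``sites`` needs columns ``site_id, lon, lat, adults, juveniles``.
    Sites outside the extent or on nodata cells are excluded with a
    warning.
    """
    cat_grid = categorize(suitability, mtss)
    records: list[SiteRecord] = []
    excluded = []
    for row in sites.itertuples(index=False):
        rc = suitability.point_to_cell(float(row.lon), float(row.lat))
        if rc is None or np.isnan(suitability.values[rc]):
            excluded.append(str(row.site_id))
            continue
        records.append(SiteRecord(
            site_id=str(row.site_id), lon=float(row.lon), lat=float(row.lat),
            suitability_value=float(suitability.values[rc]),
            category=int(cat_grid.values[rc]),
            adults=float(row.adults), juveniles=float(row.juveniles)))
    if excluded:
        warnings.warn(f"site(s) outside extent or on nodata excluded:"
                      f" {excluded}", stacklevel=2)
    return records


def compare_groups(records: list[SiteRecord], group_a: set[int],
                   group_b: set[int], parameter: str,
                   ) -> tuple[float, float, float, float]:
    """Welch t-test of a demographic parameter between category groups.

    Returns ``(mean_a, mean_b, t, p)``; for ``juveniles_per_adult``,
    adult-free sites are excluded (count reported via warning).
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}")

    def _values(group: set[int]) -> np.ndarray:
        sel = [r for r in records if r.category in group]
        if parameter == "juveniles_per_adult":
            vals = [r.juveniles_per_adult for r in sel]
            n_excl = sum(v is None for v in vals)
            if n_excl:
                warnings.warn(f"{n_excl} adult-free site(s) excluded from"
                              " juveniles_per_adult", stacklevel=3)
            return np.array([v for v in vals if v is not None])
        return np.array([getattr(r, parameter) for r in sel])

    a, b = _values(group_a), _values(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 usable records")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return float(a.mean()), float(b.mean()), 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean()), float(b.mean()), float(t), float(p)
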
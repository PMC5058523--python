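"""Synthetic landscape generation with known ground truth.

Every input the pipeline consumes can be simulated here: stacks of
spatially autocorrelated, pairwise-correlated environmental predictors, a
true suitability surface built from a known coefficient vector, occurrence
samples drawn from that surface (optionally through a sampling-bias grid),
a blob-structured forest/non-forest land-cover map, a drifting future
environmental series, and per-site demographic quadrat counts whose means
track suitability. All generators are bit-deterministic given their seed,
which is what makes parameter-recovery tests possible.

Spatial autocorrelation is produced by convolving white noise with a
uniform kernel; cross-layer correlation by linearly mixing independent
smoothed fields. Kernel smoothing is deliberately simple — no variogram
model — because recovery tests only need tunable, reproducible structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .raster import Grid, GridStack, OccurrenceSet

__all__ = [
    "LandscapeSpec",
    "TruthModel",
    "gen_env_stack",
    "true_suitability",
    "sample_occurrences",
    "gen_future_series",
    "gen_landcover",
    "gen_demography",
]


@dataclass
class LandscapeSpec:
    """Geometry and correlation structure of a simulated landscape.

    ``mixing`` is an ``n_vars x n_vars`` matrix A: the generated layers are
    ``A @ z`` for independent smoothed fields z, so the implied layer
    correlation matrix is ``corr(A A^T)``. Identity mixing gives
    independent layers.
    """

    nrows: int = 100
    ncols: int = 100
    n_vars: int = 5
    smoothing_radius: int = 3
    mixing: np.ndarray | None = None
    seed: int = 0
    xmin: float = 75.0
    ymax: float = 15.0
    cell_size: float = 0.01
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_vars < 2:
            raise ValueError("n_vars must be at least 2")
        if self.smoothing_radius < 0:
            raise ValueError("smoothing_radius must be nonnegative")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.shape != (self.n_vars, self.n_vars):
                raise ValueError(
                    f"mixing must be {self.n_vars}x{self.n_vars}, got {m.shape}")
            self.mixing = m
        if not self.layer_names:
            self.layer_names = [f"env{i + 1}" for i in range(self.n_vars)]
        elif len(self.layer_names) != self.n_vars:
            raise ValueError("layer_names length must equal n_vars")


@dataclass
class TruthModel:
    """Known generating coefficients for the true suitability surface.

    ``coefficients`` maps a layer name to ``(linear, quadratic)`` weights;
    the surface is ``logistic(intercept + sum(b1*v + b2*v^2))`` per cell.
    """

    coefficients: dict[str, tuple[float, float]]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not any(b1 != 0 or b2 != 0
                   for b1, b2 in self.coefficients.values()):
            raise ValueError("truth model needs at least one nonzero coefficient")


def _smoothed_field(rng: np.random.Generator, nrows: int, ncols: int,
                    radius: int) -> np.ndarray:
    z = rng.standard_normal((nrows, ncols))
    if radius > 0:
        z = uniform_filter(z, size=2 * radius + 1, mode="reflect")
    return z


def gen_env_stack(spec: LandscapeSpec) -> GridStack:
    """Generate the environmental predictor stack.

    Each layer is white noise convolved with a uniform kernel of the given
    radius, linearly mixed across layers by ``spec.mixing``, then
    standardized to zero mean and unit SD. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fields = np.stack([
        _smoothed_field(rng, spec.nrows, spec.ncols, spec.smoothing_radius)
        for _ in range(spec.n_vars)
    ])  # (n_vars, nrows, ncols)
    if spec.mixing is not None:
        fields = np.tensordot(spec.mixing, fields, axes=(1, 0))
    layers: dict[str, Grid] = {}
    for i, name in enumerate(spec.layer_names):
        f = fields[i]
        f = (f - f.mean()) / f.std()
        layers[name] = Grid(values=f, xmin=spec.xmin, ymax=spec.ymax,
                            cell_size=spec.cell_size)
    return GridStack(layers)


def true_suitability(stack: GridStack, truth: TruthModel) -> Grid:
    """Per-cell logistic suitability implied by the truth model."""
    missing = [n for n in truth.coefficients if n not in stack]
    if missing:
        raise ValueError(f"truth model references unknown layer(s): {missing}")
    eta = np.full(stack.ref.values.shape, float(truth.intercept))
    for name, (b1, b2) in truth.coefficients.items():
        v = stack[name].values
        eta = eta + b1 * v + b2 * v * v
    out = 1.0 / (1.0 + np.exp(-eta))
    out[~stack.mask] = np.nan
    return stack.ref.with_values(out)


def sample_occurrences(truth_surface: Grid, n: int,
                       bias: Grid | None = None, seed: int = 0,
                       species: str = "species") -> OccurrenceSet:
    """Draw occurrence cells with probability proportional to suitability x bias.

    Cells are drawn *without* replacement and points are placed at cell
    centers (so at most one occurrence per cell, matching per-cell
    thinning). ``bias`` defaults to uniform effort.
    """
    w = np.where(truth_surface.mask, truth_surface.values, 0.0).ravel()
    if bias is not None:
        truth_surface.require_alignment(bias)
        b = np.where(bias.mask, bias.values, 0.0).ravel()
        if (b < 0).any():
            raise ValueError("bias grid must be nonnegative")
        w = w * b
    positive = np.flatnonzero(w > 0)
    if n > positive.size:
        raise ValueError(
            f"requested {n} occurrences but only {positive.size} cells have"
            " positive sampling probability")
    rng = np.random.default_rng(seed)
    if n == 0:
        return OccurrenceSet(species=species, points=[])
    p = w[positive] / w[positive].sum()
    chosen = rng.choice(positive, size=n, replace=False, p=p, shuffle=False)
    pts = [truth_surface.cell_center(int(c) // truth_surface.ncols,
                                     int(c) % truth_surface.ncols)
           for c in np.sort(chosen)]
    return OccurrenceSet(species=species, points=pts)


def gen_future_series(stack: GridStack, trends: dict[str, float],
                      periods: int) -> list[GridStack]:
    """Additive-drift future series: period k layer = base + k * drift."""
    if periods < 1:
        raise ValueError("periods must be at least 1")
    unknown = [n for n in trends if n not in stack]
    if unknown:
        raise ValueError(f"trend given for unknown layer(s): {unknown}")
    series = []
    for k in range(1, periods + 1):
        layers = {}
        for name, g in stack.layers.items():
            drift = trends.get(name, 0.0)
            layers[name] = g.with_values(g.values + k * drift)
        series.append(GridStack(layers))
    return series


def gen_landcover(spec: LandscapeSpec, forest_fraction: float) -> Grid:
    """Blob-structured binary forest map with a calibrated forest share.

    A smoothed noise field is thresholded at the quantile matching
    ``forest_fraction``, giving spatially coherent forest patches whose
    share is exact up to quantile granularity.
    """
    if not 0.0 <= forest_fraction <= 1.0:
        raise ValueError("forest_fraction must be within [0, 1]")
    rng = np.random.default_rng(spec.seed + 104729)  # distinct stream
    f = _smoothed_field(rng, spec.nrows, spec.ncols,
                        max(spec.smoothing_radius, 1))
    if forest_fraction >= 1.0:
        out = np.ones_like(f)
    elif forest_fraction <= 0.0:
        out = np.zeros_like(f)
    else:
        thr = np.quantile(f, 1.0 - forest_fraction)
        out = (f > thr).astype(float)
    return Grid(values=out, xmin=spec.xmin, ymax=spec.ymax,
                cell_size=spec.cell_size)


def gen_demography(sites: list[tuple[str, float, float]], suitability: Grid,
                   effect: float, noise_sd: float, seed: int = 0,
                   base_adults: float = 5.0,
                   base_juveniles: float = 8.0) -> pd.DataFrame:
    """Simulate per-site quadrat densities that track suitability.

    Adult and juvenile densities are Gaussian draws whose means increase
    linearly with the site's suitability: ``base + effect * suitability``.
    Densities are floored at 0. Returns a table with columns
    ``site_id, lon, lat, adults, juveniles``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for site_id, lon, lat in sites:
        rc = suitability.point_to_cell(lon, lat)
        if rc is None:
            raise ValueError(f"site {site_id!r} lies outside the grid extent")
        s = suitability.values[rc]
        if np.isnan(s):
            raise ValueError(f"site {site_id!r} falls on a nodata cell")
        adults = max(0.0, base_adults + effect * s
                     + noise_sd * rng.standard_normal())
        juveniles = max(0.0, base_juveniles + effect * s
                        + noise_sd * rng.standard_normal())
        rows.append({"site_id": site_id, "lon": lon, "lat": lat,
                     "adults": adults, "juveniles": juveniles})
    return pd.DataFrame(rows)
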
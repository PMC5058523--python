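"""Dispersal-constrained range projection by cellular automaton.

Occupancy spreads step by step over a suitability raster on the integer
0–1000 scale (1000 x logistic suitability, rounded): cells at or above the
``rcThreshold`` cut are colonizable, occupied cells falling below it are
decolonized, and colonization pressure comes from *mature* occupied cells
(age >= ``iniMatAge`` steps) through a distance-indexed kernel, plus rare
long-distance dispersal (LDD) events. Barrier cells — here, land
transformed out of forest — can never be occupied. The environmental
series advances in ``encChgSteps`` periods with ``dispSteps`` automaton
steps inside each, and stochastic runs are repeated ``replicates`` times
into a consensus occupancy-frequency map.

Three bracketing scenarios are available: *unlimited* dispersal (every
suitable cell occupied each period), *none* (only initially occupied cells
persist while they stay suitable), and the *constrained* automaton proper;
the first two need no randomness and bound the third from above and below.

Cell-to-cell distance is Euclidean between centers in cell units; the
kernel is indexed by the rounded distance, so the default single-entry
kernel (probability 1 at distance 1) reaches the 8-neighborhood, distances
1 and ~1.41 both rounding to 1. The default reflects a poor disperser:
one cell per step, no long jumps unless LDD is enabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .raster import GeometryError, Grid

__all__ = [
    "DispersalParams",
    "DispersalState",
    "init_state",
    "step",
    "run",
    "suitability_to_1000",
]

SCENARIOS = ("unlimited", "none", "constrained")


def suitability_to_1000(logistic: Grid) -> Grid:
    """Round 1000 x logistic suitability onto the automaton's integer scale."""
    v = np.round(1000.0 * logistic.values)
    return logistic.with_values(v)


@dataclass
class DispersalParams:
    """Automaton parameters, named after the MIGCLIM convention.

    ``ldd_max_dist = 0`` (a published but self-contradictory setting when
    ``ldd_min_dist`` > 0) disables long-distance dispersal with a warning.
    """

    rc_threshold: float = 600.0      # suitability cut on the 0-1000 scale
    enc_chg_steps: int = 4           # environmental-change periods
    disp_steps: int = 20             # automaton steps per period
    ini_mat_age: int = 1             # steps to reproductive maturity
    propagule_prod: float = 1.0      # P(mature source emits propagules)/step
    ldd_freq: float = 0.05           # P(mature cell attempts LDD)/step
    ldd_min_dist: int = 2            # cell-distance bounds for LDD
    ldd_max_dist: int = 0
    kernel: tuple[float, ...] = (1.0,)   # P(colonize) by rounded distance 1..K
    replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rc_threshold <= 1000:
            raise ValueError("rc_threshold must be within [0, 1000]")
        for name in ("propagule_prod", "ldd_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.disp_steps < 1:
            raise ValueError("disp_steps must be at least 1")
        if any(not 0.0 <= k <= 1.0 for k in self.kernel):
            raise ValueError("kernel entries must be probabilities")

    @property
    def ldd_enabled(self) -> bool:
        return (self.ldd_freq > 0 and self.ldd_max_dist >= self.ldd_min_dist
                and self.ldd_max_dist > 0)

    def warn_if_ldd_disabled(self) -> None:
        if self.ldd_freq > 0 and not self.ldd_enabled:
            warnings.warn(
                "ldd_max_dist < ldd_min_dist: long-distance dispersal is"
                " disabled", stacklevel=2)


@dataclass
class DispersalState:
    """Occupancy, age and barrier matrices plus step counters."""

    occupied: np.ndarray          # {0,1}
    age: np.ndarray               # steps since colonization; 0 where empty
    barrier: np.ndarray           # {0,1}
    params: DispersalParams
    step_index: int = 0
    period_index: int = 0
    history: list[dict] = field(default_factory=list)

    @property
    def mature(self) -> np.ndarray:
        return (self.occupied == 1) & (self.age >= self.params.ini_mat_age)


def _as_binary(g: Grid) -> np.ndarray:
    return np.where(g.mask & (g.values == 1), 1, 0).astype(np.int8)


def init_state(initial: Grid, barrier: Grid,
               params: DispersalParams) -> DispersalState:
    """Initial occupancy: initially present cells off the barrier, mature."""
    initial.require_alignment(barrier)
    occ = _as_binary(initial) & (1 - _as_binary(barrier))
    age = np.where(occ == 1, params.ini_mat_age, 0).astype(np.int32)
    params.warn_if_ldd_disabled()
    return DispersalState(occupied=occ, age=age, barrier=_as_binary(barrier),
                          params=params)


def _kernel_footprint(kernel: tuple[float, ...]) -> np.ndarray:
    """Square array of colonization probabilities indexed by offset.

    Entry at offset (di, dj) is kernel[round(dist) - 1]; the center is 0.
    """
    k = len(kernel)
    size = 2 * k + 1
    out = np.zeros((size, size))
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            if di == 0 and dj == 0:
                continue
            d = int(round(np.hypot(di, dj)))
            if 1 <= d <= k:
                out[di + k, dj + k] = kernel[d - 1]
    return out


def step(state: DispersalState, suitability: Grid,
         rng: np.random.Generator) -> DispersalState:
    """One automaton step, in place; returns the state for chaining.

    Order of events: decolonization of unsuitable cells, short-distance
    colonization from mature sources through the kernel, long-distance
    dispersal, then aging. Newly colonized cells start at age 1; initially
    occupied cells were seeded mature.
    """
    p = state.params
    suit = suitability.values
    if np.nanmin(suit) < 0 or np.nanmax(suit) > 1000:
        raise ValueError("suitability must be on the 0-1000 scale")
    suitable = state.barrier == 0
    suitable &= np.where(np.isnan(suit), False, suit >= p.rc_threshold)

    # (a) decolonization
    lost = (state.occupied == 1) & ~suitable
    state.occupied[lost] = 0
    state.age[lost] = 0

    mature = state.mature.astype(float)
    open_cells = (state.occupied == 0) & suitable

    # (b) short-distance colonization: P = 1 - prod over sources in range of
    #     (1 - propagule_prod * kernel(d)), computed by log-space convolution
    colonized = np.zeros_like(state.occupied, dtype=bool)
    if open_cells.any() and mature.any():
        pk = p.propagule_prod * _kernel_footprint(p.kernel)
        sure = pk >= 1.0
        with np.errstate(divide="ignore"):
            log_miss = np.where(sure, 0.0, np.log1p(-pk))
        ll = convolve(mature, log_miss[::-1, ::-1], mode="constant", cval=0.0)
        p_col = 1.0 - np.exp(ll)
        if sure.any():
            hit = convolve(mature, sure[::-1, ::-1].astype(float),
                           mode="constant", cval=0.0) > 0.5
            p_col = np.where(hit, 1.0, p_col)
        draw = rng.random(p_col.shape)
        colonized = open_cells & (draw < p_col)

    # (c) long-distance dispersal
    if p.ldd_enabled and mature.any():
        sources = np.argwhere(mature > 0)
        attempts = rng.random(len(sources)) < p.ldd_freq
        nrows, ncols = state.occupied.shape
        for (si, sj) in sources[attempts]:
            cand = []
            dmax = p.ldd_max_dist
            for di in range(-dmax, dmax + 1):
                for dj in range(-dmax, dmax + 1):
                    d = int(round(np.hypot(di, dj)))
                    if not p.ldd_min_dist <= d <= p.ldd_max_dist:
                        continue
                    ti, tj = si + di, sj + dj
                    if (0 <= ti < nrows and 0 <= tj < ncols
                            and open_cells[ti, tj] and not colonized[ti, tj]):
                        cand.append((ti, tj))
            if cand:
                ti, tj = cand[rng.integers(len(cand))]
                colonized[ti, tj] = True

    # (d) aging and bookkeeping
    state.age[state.occupied == 1] += 1
    state.occupied[colonized] = 1
    state.age[colonized] = 1
    state.step_index += 1
    state.history.append({
        "period": state.period_index, "step": state.step_index,
        "colonized": int(colonized.sum()), "decolonized": int(lost.sum()),
        "occupied": int(state.occupied.sum()),
    })
    return state


def run(initial: Grid, barrier: Grid, suitability_series: list[Grid],
        params: DispersalParams, scenario: str = "constrained",
        ) -> tuple[list[Grid], pd.DataFrame]:
    """Project occupancy through the environmental series.

    Returns one occupancy map per period plus the per-step history table.
    Under the constrained scenario the maps are consensus frequencies over
    ``params.replicates`` stochastic runs (range [0, 1]); the unlimited
    and none scenarios are deterministic and return binary maps.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if len(suitability_series) != params.enc_chg_steps:
        raise ValueError(
            f"series length {len(suitability_series)} != enc_chg_steps"
            f" {params.enc_chg_steps}")
    initial.require_alignment(barrier)
    for s in suitability_series:
        initial.require_alignment(s)

    ini = _as_binary(initial)
    if scenario == "unlimited":
        out = []
        for s in suitability_series:
            occ = np.where(np.isnan(s.values), 0,
                           (s.values >= params.rc_threshold)).astype(float)
            out.append(initial.with_values(occ))
        return out, pd.DataFrame()

    if scenario == "none":
        out = []
        for s in suitability_series:
            occ = ini & np.where(np.isnan(s.values), 0,
                                 s.values >= params.rc_threshold)
            out.append(initial.with_values(occ.astype(float)))
        return out, pd.DataFrame()

    ss = np.random.SeedSequence(params.seed)
    consensus = [np.zeros(ini.shape) for _ in suitability_series]
    histories = []
    for rep, child in enumerate(ss.spawn(params.replicates)):
        rng = np.random.default_rng(child)
        state = init_state(initial, barrier, params)
        for k, suit in enumerate(suitability_series):
            state.period_index = k + 1
            for _ in range(params.disp_steps):
                step(state, suit, rng)
            consensus[k] += state.occupied
        h = pd.DataFrame(state.history)
        h["replicate"] = rep
        histories.append(h)
    out = [initial.with_values(c / params.replicates) for c in consensus]
    history = pd.concat(histories, ignore_index=True)
    return out, history
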
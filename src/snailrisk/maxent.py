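"""Presence-background maximum-entropy suitability model.

The model fits a Gibbs (exponential-family) distribution over landscape
cells: ``q(x) = exp(sum_j lambda_j f_j(x)) / Z`` with Z normalizing over a
background sample standing in for the available environment. The
coefficients maximize the penalized mean presence log-likelihood

    mean_p [eta(x_p)] - log Z(lambda) - beta * sum_j |lambda_j| / sqrt(m)

with m the number of presence cells — the lasso-style penalty keeps
coefficients of uninformative features at exactly zero. Features are
linear, quadratic and pairwise-product transforms of the predictor layers,
standardized to background mean 0 / SD 1; the objective is convex, so a
deterministic proximal-Newton coordinate sweep converges to the unique
optimum regardless of the starting point.

Suitability is reported either *raw* (the Gibbs density, summing to one
over the background sample) or *logistic*: ``r e^H / (1 + r e^H)`` with H
the entropy of the fitted background distribution, which maps a cell of
typical suitability to about 0.5 and is the scale every downstream
threshold assumes.

Diagnostics mirror standard niche-modeling practice: per-variable percent
contribution (objective gain accrued during fitting), permutation
importance (drop in training AUC when a predictor's values are shuffled),
jackknife gains (refit with each variable alone / excluded), and marginal
response curves.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .evalmetrics import auc, mtss_threshold, tss_at
from .raster import Grid, GridStack, OccurrenceSet

__all__ = [
    "FeatureSpec",
    "SuitabilityModel",
    "ReplicateEvaluation",
    "sample_background",
    "fit",
    "predict",
    "predict_cells",
    "replicate_evaluate",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
]

_ALLOWED_TYPES = ("linear", "quadratic", "product")


@dataclass
class FeatureSpec:
    """Which feature transforms of the predictors enter the model."""

    types: tuple[str, ...] = ("linear", "quadratic", "product")

    def __post_init__(self) -> None:
        bad = [t for t in self.types if t not in _ALLOWED_TYPES]
        if bad:
            raise ValueError(f"unknown feature type(s): {bad}")
        if not self.types:
            raise ValueError("at least one feature type must be enabled")

    def build_terms(self, var_names: list[str]) -> list[tuple]:
        """Feature terms as ('linear', i) / ('quadratic', i) / ('product', i, j)."""
        terms: list[tuple] = []
        n = len(var_names)
        if "linear" in self.types:
            terms += [("linear", i) for i in range(n)]
        if "quadratic" in self.types:
            terms += [("quadratic", i) for i in range(n)]
        if "product" in self.types:
            terms += [("product", i, j) for i in range(n)
                      for j in range(i + 1, n)]
        return terms


def _term_name(term: tuple, var_names: list[str]) -> str:
    if term[0] == "linear":
        return var_names[term[1]]
    if term[0] == "quadratic":
        return f"{var_names[term[1]]}^2"
    return f"{var_names[term[1]]}*{var_names[term[2]]}"


def _raw_features(x: np.ndarray, terms: list[tuple]) -> np.ndarray:
    cols = []
    for term in terms:
        if term[0] == "linear":
            cols.append(x[:, term[1]])
        elif term[0] == "quadratic":
            cols.append(x[:, term[1]] ** 2)
        else:
            cols.append(x[:, term[1]] * x[:, term[2]])
    return np.column_stack(cols) if cols else np.empty((x.shape[0], 0))


@dataclass
class SuitabilityModel:
    """A fitted presence-background exponential model."""

    var_names: list[str]
    feature_spec: FeatureSpec
    terms: list[tuple]
    lambdas: np.ndarray          # per standardized feature
    means: np.ndarray            # feature standardization (from background)
    scales: np.ndarray
    log_partition: float         # log sum over background of exp(eta)
    entropy_H: float             # entropy of fitted background distribution
    reg_beta: float
    n_presence: int
    gain: float                  # unpenalized training gain over null model
    objective: float = np.nan    # final penalized objective (minimized)
    gain_trace: dict[str, float] = field(default_factory=dict)
    var_means: np.ndarray | None = None   # raw per-variable background stats
    var_min: np.ndarray | None = None
    var_max: np.ndarray | None = None

    @property
    def feature_names(self) -> list[str]:
        return [_term_name(t, self.var_names) for t in self.terms]

    def linear_predictor(self, x_raw: np.ndarray) -> np.ndarray:
        """eta for raw predictor rows (columns ordered as var_names)."""
        f = _raw_features(x_raw, self.terms)
        z = (f - self.means) / self.scales
        return z @ self.lambdas

    # -- plain-text serialization ----------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# snailrisk suitability model\n")
        buf.write(f"log_partition {self.log_partition!r}\n")
        buf.write(f"entropy_H {self.entropy_H!r}\n")
        buf.write(f"reg_beta {self.reg_beta!r}\n")
        buf.write(f"n_presence {self.n_presence}\n")
        buf.write(f"gain {self.gain!r}\n")
        buf.write("feature\tlambda\tmean\tscale\n")
        for name, lam, mu, sc in zip(self.feature_names, self.lambdas,
                                     self.means, self.scales):
            buf.write(f"{name}\t{lam!r}\t{mu!r}\t{sc!r}\n")
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


@dataclass
class ReplicateEvaluation:
    """Per-replicate and summary AUC/TSS/MTSS statistics."""

    per_replicate: pd.DataFrame  # auc_train, auc_test, tss, mtss_threshold

    @property
    def summary(self) -> pd.DataFrame:
        return self.per_replicate.agg(["mean", "std"]).fillna(0.0)

    def formatted(self) -> dict[str, str]:
        """'mean (SD)' strings, the conventional reporting format."""
        s = self.summary
        return {c: f"{s.loc['mean', c]:.3f} ({s.loc['std', c]:.3f})"
                for c in self.per_replicate.columns}


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_background(stack: GridStack, n: int, bias: Grid | None = None,
                      seed: int = 0) -> np.ndarray:
    """Draw background cells without replacement, probability ∝ bias.

    Returns flat cell indices into the stack's grid. Uniform effort when
    no bias grid is given.
    """
    cells = stack.data_cells()
    if bias is not None:
        stack.ref.require_alignment(bias)
        w = np.where(bias.mask, bias.values, 0.0).ravel()[cells]
        if (w < 0).any():
            raise ValueError("bias grid must be nonnegative")
        pos = w > 0
        cells, w = cells[pos], w[pos]
    else:
        w = np.ones(cells.size)
    if n > cells.size:
        raise ValueError(
            f"requested {n} background cells but only {cells.size} available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cells, size=n, replace=False, p=w / w.sum(),
                        shuffle=False)
    return np.sort(chosen)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _objective(lam: np.ndarray, zp: np.ndarray, zb: np.ndarray,
               alpha: float) -> float:
    eta_b = zb @ lam
    return float(logsumexp(eta_b) - (zp @ lam).mean()
                 + alpha * np.abs(lam).sum())


def _presence_cells(presences, stack: GridStack) -> np.ndarray:
    if isinstance(presences, OccurrenceSet):
        return presences.to_cells(stack.ref, thin=True)
    return np.unique(np.asarray(presences, dtype=np.intp))


def fit(presences, background: np.ndarray, stack: GridStack,
        spec: FeatureSpec | None = None, reg_beta: float = 1.0,
        seed: int = 0, *, max_cycles: int = 10_000, tol: float = 1e-8,
        lam0: np.ndarray | None = None) -> SuitabilityModel:
    """Fit the penalized maximum-entropy model.

    ``presences`` may be an :class:`OccurrenceSet` (thinned to one record
    per cell) or an array of flat cell indices; ``background`` is an array
    of flat cell indices, e.g. from :func:`sample_background`. The
    optimizer is a deterministic cyclic proximal-Newton coordinate sweep
    with soft-thresholding for the L1 penalty and per-coordinate
    backtracking; ``seed`` never affects the optimization itself, only
    callers' sampling. The objective is convex, so runs from different
    ``lam0`` starting points agree at the optimum.
    """
    spec = spec or FeatureSpec()
    p_cells = _presence_cells(presences, stack)
    if p_cells.size < 5:
        raise ValueError("need at least 5 presence cells after thinning")
    background = np.asarray(background, dtype=np.intp)

    var_names = stack.names
    xp = stack.matrix(p_cells)
    xb = stack.matrix(background)
    for j, name in enumerate(var_names):
        if not np.isfinite(xp[:, j]).all() or not np.isfinite(xb[:, j]).all():
            raise ValueError(f"non-finite values in layer '{name}'")

    terms = spec.build_terms(var_names)
    fp = _raw_features(xp, terms)
    fb = _raw_features(xb, terms)
    means = fb.mean(axis=0)
    scales = fb.std(axis=0)
    scales[scales == 0] = 1.0  # constant feature: stays at lambda = 0
    zp = (fp - means) / scales
    zb = (fb - means) / scales

    m = p_cells.size
    alpha = reg_beta / np.sqrt(m)
    k = len(terms)
    lam = np.zeros(k) if lam0 is None else np.asarray(lam0, dtype=float).copy()

    eta_b = zb @ lam
    mean_zp = zp.mean(axis=0)
    obj = _objective(lam, zp, zb, alpha)
    gain_by_feature = np.zeros(k)

    for cycle in range(max_cycles):
        obj_start = obj
        for j in range(k):
            w = np.exp(eta_b - logsumexp(eta_b))
            bj = zb[:, j]
            mu = float(w @ bj)
            var = float(w @ (bj * bj) - mu * mu)
            g = mu - mean_zp[j]
            h = max(var, 1e-12)
            z = lam[j] - g / h
            new = np.sign(z) * max(abs(z) - alpha / h, 0.0)
            delta = new - lam[j]
            if delta == 0.0:
                continue
            # damped proximal-Newton step with backtracking on the objective
            for _ in range(20):
                cand = lam[j] + delta
                eta_try = eta_b + delta * bj
                obj_try = float(logsumexp(eta_try)
                                - ((zp @ lam) + delta * zp[:, j]).mean()
                                + alpha * (np.abs(lam).sum()
                                           - abs(lam[j]) + abs(cand)))
                if obj_try <= obj + 1e-15:
                    gain_by_feature[j] += obj - obj_try
                    lam[j] = cand
                    eta_b = eta_try
                    obj = obj_try
                    break
                delta *= 0.5
        if obj_start - obj <= tol * (1.0 + abs(obj_start)):
            break
    else:
        warnings.warn("maxent fit reached the iteration cap before the"
                      " requested tolerance", stacklevel=2)

    log_z = float(logsumexp(eta_b))
    q = np.exp(eta_b - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-(q * np.where(q > 0, np.log(q), 0.0)).sum())
    # training gain relative to the uniform null model, unpenalized
    loglik = float((zp @ lam).mean() - log_z)
    gain = loglik - (-np.log(background.size))

    trace: dict[str, float] = {n: 0.0 for n in var_names}
    for term, gval in zip(terms, gain_by_feature):
        if term[0] in ("linear", "quadratic"):
            trace[var_names[term[1]]] += gval
        else:  # product features split evenly between their two variables
            trace[var_names[term[1]]] += gval / 2.0
            trace[var_names[term[2]]] += gval / 2.0

    return SuitabilityModel(
        var_names=var_names, feature_spec=spec, terms=terms, lambdas=lam,
        means=means, scales=scales, log_partition=log_z,
        entropy_H=entropy, reg_beta=reg_beta, n_presence=m,
        gain=max(gain, 0.0), objective=obj, gain_trace=trace,
        var_means=xb.mean(axis=0), var_min=xb.min(axis=0),
        var_max=xb.max(axis=0))


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _logistic_from_raw(raw: np.ndarray, entropy_h: float) -> np.ndarray:
    r = raw * np.exp(entropy_h)
    return r / (1.0 + r)


def predict_cells(model: SuitabilityModel, stack: GridStack,
                  cells: np.ndarray, output: str = "logistic") -> np.ndarray:
    """Suitability scores at specific flat cell indices."""
    x = stack.subset(model.var_names).matrix(np.asarray(cells, dtype=np.intp))
    eta = model.linear_predictor(x)
    raw = np.exp(eta - model.log_partition)
    if output == "raw":
        return raw
    if output == "logistic":
        return _logistic_from_raw(raw, model.entropy_H)
    raise ValueError("output must be 'raw' or 'logistic'")


def predict(model: SuitabilityModel, stack: GridStack,
            output: str = "logistic") -> Grid:
    """Suitability map over every data cell of the stack."""
    missing = [n for n in model.var_names if n not in stack]
    if missing:
        raise ValueError(f"stack is missing model layer(s): {missing}")
    cells = stack.data_cells()
    scores = predict_cells(model, stack, cells, output=output)
    out = np.full(stack.ref.values.shape, np.nan).ravel()
    out[cells] = scores
    return stack.ref.with_values(out.reshape(stack.ref.values.shape))


# ---------------------------------------------------------------------------
# Replicate evaluation
# ---------------------------------------------------------------------------

def replicate_evaluate(presences, stack: GridStack,
                       spec: FeatureSpec | None = None,
                       reg_beta: float = 1.0, n_replicates: int = 10,
                       test_fraction: float = 0.3, seed: int = 0,
                       background_n: int = 10_000,
                       bias: Grid | None = None) -> ReplicateEvaluation:
    """Random presence splits with fresh background per replicate.

    Each replicate holds out ``test_fraction`` of the (thinned) presences,
    fits on the rest, and reports training/test AUC against the background
    sample plus the TSS of the held-out presences at the training MTSS
    threshold.
    """
    p_cells = _presence_cells(presences, stack)
    n_test = int(round(test_fraction * p_cells.size))
    if n_test < 3 or p_cells.size - n_test < 5:
        raise ValueError("not enough presences for the requested split")
    background_n = min(background_n, stack.data_cells().size)
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(p_cells.size)
        test = p_cells[perm[:n_test]]
        train = p_cells[perm[n_test:]]
        bg = sample_background(stack, background_n, bias=bias,
                               seed=int(child.generate_state(1)[0] % 2**31))
        model = fit(train, bg, stack, spec=spec, reg_beta=reg_beta)
        s_train = predict_cells(model, stack, train)
        s_test = predict_cells(model, stack, test)
        s_bg = predict_cells(model, stack, bg)
        search = mtss_threshold(s_train, s_bg)
        rows.append({
            "auc_train": auc(s_train, s_bg),
            "auc_test": auc(s_test, s_bg),
            "tss": tss_at(s_test, s_bg, search.mtss_threshold),
            "mtss_threshold": search.mtss_threshold,
        })
    return ReplicateEvaluation(per_replicate=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def percent_contribution(model: SuitabilityModel) -> pd.DataFrame:
    """Objective gain accrued per variable during fitting, normalized to 100."""
    if not model.gain_trace or all(v == 0 for v in model.gain_trace.values()):
        raise ValueError("model carries no fitting trace (null model?)")
    total = sum(model.gain_trace.values())
    rows = [{"variable": n, "percent_contribution": 100.0 * v / total}
            for n, v in sorted(model.gain_trace.items(),
                               key=lambda kv: -kv[1])]
    return pd.DataFrame(rows)


def permutation_importance(model: SuitabilityModel, presences,
                           background: np.ndarray, stack: GridStack,
                           seed: int = 0) -> pd.DataFrame:
    """Drop in training AUC when one predictor's values are shuffled.

    The variable's raw values are permuted jointly across the evaluation
    cells (presences plus background); drops are floored at zero and
    normalized to sum to 100.
    """
    p_cells = _presence_cells(presences, stack)
    background = np.asarray(background, dtype=np.intp)
    cells = np.concatenate([p_cells, background])
    x = stack.subset(model.var_names).matrix(cells)
    rng = np.random.default_rng(seed)

    def _auc_of(xmat: np.ndarray) -> float:
        eta = model.linear_predictor(xmat)
        return auc(eta[:p_cells.size], eta[p_cells.size:])

    base = _auc_of(x)
    drops = []
    for j, name in enumerate(model.var_names):
        xp = x.copy()
        xp[:, j] = rng.permutation(xp[:, j])
        drops.append(max(0.0, base - _auc_of(xp)))
    total = sum(drops)
    shares = [100.0 * d / total if total > 0 else 0.0 for d in drops]
    df = pd.DataFrame({"variable": model.var_names,
                       "permutation_importance": shares})
    return df.sort_values("permutation_importance", ascending=False,
                          ignore_index=True)


def jackknife_gains(presences, stack: GridStack,
                    spec: FeatureSpec | None = None, reg_beta: float = 1.0,
                    seed: int = 0, background_n: int = 10_000,
                    test_fraction: float = 0.3) -> pd.DataFrame:
    """Refit with each variable alone and with each variable excluded.

    Reports training gain in both conditions and the test AUC of the
    single-variable model; the full-model gain is attached as
    ``df.attrs['full_gain']``.
    """
    if len(stack) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    p_cells = _presence_cells(presences, stack)
    rng = np.random.default_rng(seed)
    n_test = max(3, int(round(test_fraction * p_cells.size)))
    perm = rng.permutation(p_cells.size)
    test, train = p_cells[perm[:n_test]], p_cells[perm[n_test:]]
    background_n = min(background_n, stack.data_cells().size)
    bg = sample_background(stack, background_n, seed=seed)

    def _gain(sub: GridStack, cells_train):
        return fit(cells_train, bg, sub, spec=spec, reg_beta=reg_beta)

    full = _gain(stack, train)
    rows = []
    for name in stack.names:
        only = _gain(stack.subset([name]), train)
        rest = _gain(stack.subset([n for n in stack.names if n != name]),
                     train)
        s_test = predict_cells(only, stack, test)
        s_bg = predict_cells(only, stack, bg)
        rows.append({"variable": name, "gain_only": only.gain,
                     "gain_without": rest.gain,
                     "test_auc_only": auc(s_test, s_bg)})
    df = pd.DataFrame(rows)
    df.attrs["full_gain"] = full.gain
    return df


def response_curve(model: SuitabilityModel, stack: GridStack,
                   variable: str, n_points: int = 100) -> pd.DataFrame:
    """Marginal response: sweep one predictor, others at background means."""
    if variable not in model.var_names:
        raise ValueError(f"variable '{variable}' not in model")
    j = model.var_names.index(variable)
    lo, hi = model.var_min[j], model.var_max[j]
    sweep = np.linspace(lo, hi, n_points)
    x = np.tile(model.var_means, (n_points, 1))
    x[:, j] = sweep
    eta = model.linear_predictor(x)
    raw = np.exp(eta - model.log_partition)
    return pd.DataFrame({"value": sweep,
                         "logistic": _logistic_from_raw(raw, model.entropy_H)})
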
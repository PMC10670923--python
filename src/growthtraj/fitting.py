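"""Nonlinear least-squares fitting of one trait series to one growth law.

Fits are ordinary (independent-Gaussian) nonlinear least squares with
self-start initialization, bound enforcement by smooth reparameterization
(log for positive parameters, logit for the Gompertz 0 < c < 1 shape
parameter) and seeded multi-start restarts on non-convergence. The Gaussian
log-likelihood is concentrated over sigma^2:

    sigma2_hat = SSE / n
    logL = -(n / 2) * (ln(2 * pi * sigma2_hat) + 1)

Information criteria follow the full-Gaussian-likelihood convention with
k = n_params + 1 free parameters (sigma counted), matching R's ``AIC`` on an
``nls`` fit:

    AIC = n ln(2 pi sigma2_hat) + n + 2 k
    BIC = n ln(2 pi sigma2_hat) + n + k ln(n)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .growth_models import (
    GrowthModel,
    MODEL_SPECS,
    eval_model,
    validate_params,
)

__all__ = [
    "TraitSeries",
    "FitResult",
    "FitMetrics",
    "NonFittableError",
    "initial_guess",
    "fit_growth_curve",
    "fit_pooled",
    "compute_metrics",
    "gaussian_loglik",
]

#: floor applied to sigma2_hat so that perfect (sse = 0) fits keep a finite
#: log-likelihood
SIGMA2_FLOOR = 1e-12

#: relative SSE change below which the optimizer is considered converged
FTOL = 1e-10

#: maximum optimizer iterations (function evaluations budget per start)
MAX_ITER = 500

#: maximum number of jittered restarts on non-convergence
MAX_RESTARTS = 10

#: sd of the multiplicative lognormal jitter applied to restart initials
RESTART_JITTER_SD = 0.3


class NonFittableError(ValueError):
    """The series carries no usable signal for curve fitting."""


@dataclass(frozen=True)
class TraitSeries:
    """Repeated measures of one trait on one clone (long-format row group)."""

    clone_id: str
    trait: str  # "height_m" or "dbh_cm"
    ages: np.ndarray  # years, strictly increasing
    values: np.ndarray  # trait units, positive

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.ndim != 1 or values.shape != ages.shape:
            raise ValueError("ages and values must be 1-d arrays of equal length")
        if len(ages) < 4:
            raise ValueError("need at least 4 observations (3 curve parameters)")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("ages must be strictly increasing")
        if not np.all(values > 0):
            raise ValueError("trait values must be positive")

    @property
    def n(self) -> int:
        return len(self.ages)


@dataclass
class FitResult:
    """One growth-law fit to one trait series (or a pooled set of series)."""

    model: GrowthModel
    params: np.ndarray
    sse: float
    n: int
    converged: bool
    n_restarts_used: int = 0
    clone_id: str | None = None
    trait: str | None = None

    @property
    def sigma2_hat(self) -> float:
        return max(self.sse / self.n, SIGMA2_FLOOR)

    @property
    def loglik(self) -> float:
        return gaussian_loglik(self.sse, self.n)

    def predict(self, t):
        return eval_model(self.model, self.params, t)

    def param_dict(self) -> dict[str, float]:
        names = MODEL_SPECS[self.model].param_names
        return dict(zip(names, map(float, self.params)))


@dataclass(frozen=True)
class FitMetrics:
    """The five goodness-of-fit metrics used to rank growth laws."""

    aic: float
    bic: float
    r2: float
    rmse: float
    mae: float


def gaussian_loglik(sse: float, n: int) -> float:
    """Concentrated Gaussian log-likelihood of a least-squares fit."""
    sigma2 = max(sse / n, SIGMA2_FLOOR)
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


# --------------------------------------------------------------------------
# parameter transforms: optimizer works in an unconstrained space z
# --------------------------------------------------------------------------


def _to_unconstrained(model: GrowthModel, p: np.ndarray) -> np.ndarray:
    a, b, c = p
    if model is GrowthModel.GOMPERTZ:
        return np.array([math.log(a), math.log(b), math.log(c / (1.0 - c))])
    if model is GrowthModel.RICHARD:
        return np.log(p)
    if model is GrowthModel.LOGISTIC:
        return np.array([math.log(a), b, math.log(c)])  # Asym, xmid, scal
    # asymptotic: a = b + exp(z0), b = exp(z1) - 1e-9 kept simple: b > 0 in practice
    return np.array([math.log(a - b), math.log(max(b, 1e-9)), c])


def _from_unconstrained(model: GrowthModel, z: np.ndarray) -> np.ndarray:
    z0, z1, z2 = z
    if model is GrowthModel.GOMPERTZ:
        return np.array([math.exp(z0), math.exp(z1), 1.0 / (1.0 + math.exp(-z2))])
    if model is GrowthModel.RICHARD:
        return np.exp(z)
    if model is GrowthModel.LOGISTIC:
        return np.array([math.exp(z0), z1, math.exp(z2)])
    return np.array([math.exp(z1) + math.exp(z0), math.exp(z1), z2])


# --------------------------------------------------------------------------
# self-start heuristics
# --------------------------------------------------------------------------


def initial_guess(series: TraitSeries, model: GrowthModel | str) -> np.ndarray:
    """Self-start parameter heuristics for one growth law.

    Amplitude is 1.05 * max(values); rate/shape parameters come from crude
    log-linearizations. The returned vector always satisfies the model's
    parameter constraints.
    """
    model = GrowthModel(model)
    t, y = series.ages, series.values
    if np.ptp(y) <= 0:
        raise NonFittableError(
            f"constant series for clone {series.clone_id!r}: nothing to fit"
        )
    amp = 1.05 * float(y.max())

    if model is GrowthModel.LOGISTIC:
        xmid = float(t[np.argmin(np.abs(y - amp / 2.0))])
        scal = max(float(np.ptp(t)) / 4.0, 1e-3)
        # undo the logistic's remaining headroom at the last observation
        amp = float(
            np.clip(
                y[-1] * (1.0 + math.exp((xmid - t[-1]) / scal)),
                amp,
                3.0 * y.max(),
            )
        )
        return validate_params(model, [amp, xmid, scal])

    if model is GrowthModel.GOMPERTZ:
        # b c^t = ln(a / y): two-point solve on first and last observation
        g1 = max(math.log(amp / y[0]), 1e-6)
        g2 = max(math.log(amp / y[-1]), 1e-6)
        dt = float(t[-1] - t[0])
        c = float(np.clip((g2 / g1) ** (1.0 / dt), 0.05, 0.95))
        b = float(np.clip(g1 / c ** float(t[0]), 1e-3, 50.0))
        return validate_params(model, [amp, b, c])

    if model is GrowthModel.RICHARD:
        # assume a mildly sigmoid shape c0 and back out b at mid-series
        c0 = 1.5
        i = len(t) // 2
        frac = float(np.clip((y[i] / amp) ** (1.0 / c0), 1e-6, 1.0 - 1e-6))
        b = float(np.clip(-math.log(1.0 - frac) / float(t[i]), 1e-3, 20.0))
        return validate_params(model, [amp, b, c0])

    # asymptotic: b is the value at t = 0, exp(c) the decay rate
    b0 = float(min(y[0], 0.9 * amp))
    i = len(t) // 2
    frac = float(np.clip((amp - y[i]) / (amp - b0), 1e-6, 1.0 - 1e-6))
    rate = max(-math.log(frac) / float(t[i]), 1e-4)
    return validate_params(model, [amp, b0, math.log(rate)])


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _residual_fn(model: GrowthModel, t: np.ndarray, y: np.ndarray):
    def resid(z):
        p = _from_unconstrained(model, z)
        with np.errstate(over="ignore", invalid="ignore"):
            pred = eval_model(model, p, t)
        pred = np.nan_to_num(pred, nan=1e6, posinf=1e6, neginf=-1e6)
        return pred - y

    return resid


def _ls_once(model: GrowthModel, t, y, p0: np.ndarray):
    z0 = _to_unconstrained(model, np.asarray(p0, dtype=float))
    res = least_squares(
        _residual_fn(model, t, y),
        z0,
        method="lm",
        ftol=FTOL,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=MAX_ITER * 4,
    )
    params = _from_unconstrained(model, res.x)
    sse = float(np.sum(res.fun**2))
    return params, sse, bool(res.status > 0)


def fit_growth_curve(
    series: TraitSeries,
    model: GrowthModel | str,
    init: Sequence[float] | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit one growth law to one trait series by nonlinear least squares.

    Uses the self-start heuristics unless `init` is given; on non-convergence
    retries up to 10 restarts with seeded multiplicative lognormal jitter
    (sd 0.3) on the initial parameters and returns the best SSE found. A fit
    that never converges is returned with ``converged=False`` (best-effort
    parameters), never silently dropped.
    """
    model = GrowthModel(model)
    t = np.asarray(series.ages, dtype=float)
    y = np.asarray(series.values, dtype=float)
    return _fit_points(model, t, y, init=init, seed=seed,
                       clone_id=series.clone_id, trait=series.trait,
                       heuristic_series=series)


def fit_pooled(
    series_list: Sequence[TraitSeries],
    model: GrowthModel | str,
    seed: int = 0,
) -> FitResult:
    """Fit a single curve to the pooled observations of several clones.

    This is the restricted (one-curve) model of the likelihood-ratio
    trajectory test: all member clones' points enter one least-squares
    problem.
    """
    model = GrowthModel(model)
    t = np.concatenate([np.asarray(s.ages, float) for s in series_list])
    y = np.concatenate([np.asarray(s.values, float) for s in series_list])
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    # self-start on the age-wise mean profile
    ages = np.unique(t)
    means = np.array([y[t == age].mean() for age in ages])
    ref = TraitSeries("__pooled__", series_list[0].trait, ages, np.maximum(means, 1e-9))
    return _fit_points(model, t, y, init=None, seed=seed,
                       clone_id="__pooled__", trait=series_list[0].trait,
                       heuristic_series=ref)


def _fit_points(model, t, y, *, init, seed, clone_id, trait, heuristic_series):
    p0 = np.asarray(init, float) if init is not None else initial_guess(heuristic_series, model)
    validate_params(model, p0)
    sse0 = float(np.sum((np.asarray(eval_model(model, p0, t)) - y) ** 2))

    rng = np.random.default_rng(seed)
    best = None
    n_restarts = 0
    start = p0
    for attempt in range(MAX_RESTARTS + 1):
        try:
            params, sse, ok = _ls_once(model, t, y, start)
            validate_params(model, params)
        except Exception:
            ok, params, sse = False, None, math.inf
        if params is not None and (best is None or sse < best[1]):
            best = (params, sse, ok)
        if best is not None and best[2] and best[1] <= sse0 + 1e-12:
            break
        n_restarts = attempt + 1
        z = _to_unconstrained(model, p0)
        start = _from_unconstrained(model, z + rng.normal(0.0, RESTART_JITTER_SD, 3))

    if best is None:  # every start failed outright: report the initial guess
        return FitResult(model, p0, sse0, len(y), False, n_restarts, clone_id, trait)
    params, sse, ok = best
    if sse > sse0:  # never return something worse than the self-start
        params, sse = p0, sse0
    return FitResult(model, params, sse, len(y), ok, n_restarts, clone_id, trait)


def compute_metrics(fit: FitResult, series: TraitSeries) -> FitMetrics:
    """The five goodness-of-fit metrics (AIC, BIC, R2, RMSE, MAE) of a fit."""
    y = np.asarray(series.values, dtype=float)
    resid = y - np.asarray(fit.predict(series.ages), dtype=float)
    sse = float(np.sum(resid**2))
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise NonFittableError("zero total variance: R2 undefined")
    k = MODEL_SPECS[fit.model].n_params + 1  # sigma counted
    sigma2 = max(sse / n, SIGMA2_FLOOR)
    aic = n * math.log(2 * math.pi * sigma2) + n + 2 * k
    bic = n * math.log(2 * math.pi * sigma2) + n + k * math.log(n)
    return FitMetrics(
        aic=aic,
        bic=bic,
        r2=1.0 - sse / sst,
        rmse=math.sqrt(sse / n),
        mae=float(np.mean(np.abs(resid))),
    )
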
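"""Parametric growth laws for perennial tree traits.

Four three-parameter sigmoidal / saturating growth laws commonly used for
cumulative tree height and diameter at breast height (DBH):

====================  ====================================  ==================
model                 y(t)                                  parameters
====================  ====================================  ==================
gompertz              a * exp(-b * c**t)                    a > 0, b > 0, 0 < c < 1
richard               a * (1 - exp(-b*t))**c                a > 0, b > 0, c > 0
                      (Chapman-Richards; sigmoid for c > 1)
logistic              Asym / (1 + exp((xmid - t) / scal))   Asym > 0, scal > 0
asymptotic            a + (b - a) * exp(-exp(c) * t)        a > b >= 0, c real
====================  ====================================  ==================

`a` / `Asym` is the growth plateau (trait units: m for height, cm for DBH);
the remaining parameters control rate and timing (1/years or years). Time is
measured in years from planting, t >= 0. All evaluators are vectorized over t
and return analytic values -- the first and second time derivatives are
closed-form, which downstream curvature analysis relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthModel",
    "GrowthModelSpec",
    "MODEL_SPECS",
    "InvalidParameterError",
    "DivergentModelError",
    "validate_params",
    "eval_model",
    "eval_derivatives",
    "time_of_max_growth",
    "asymptote",
]


class GrowthModel(str, Enum):
    """Identifier for one of the four supported growth laws."""

    GOMPERTZ = "gompertz"
    RICHARD = "richard"
    LOGISTIC = "logistic"
    ASYMPTOTIC = "asymptotic"


@dataclass(frozen=True)
class GrowthModelSpec:
    """Static description of a growth law: its id and parameter layout."""

    model_id: GrowthModel
    param_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


MODEL_SPECS: dict[GrowthModel, GrowthModelSpec] = {
    GrowthModel.GOMPERTZ: GrowthModelSpec(GrowthModel.GOMPERTZ, ("a", "b", "c")),
    GrowthModel.RICHARD: GrowthModelSpec(GrowthModel.RICHARD, ("a", "b", "c")),
    GrowthModel.LOGISTIC: GrowthModelSpec(GrowthModel.LOGISTIC, ("Asym", "xmid", "scal")),
    GrowthModel.ASYMPTOTIC: GrowthModelSpec(GrowthModel.ASYMPTOTIC, ("a", "b", "c")),
}


class InvalidParameterError(ValueError):
    """A parameter vector violates the model's domain constraints."""


class DivergentModelError(ValueError):
    """The model has no finite plateau for these parameters."""


def _as_model(model: GrowthModel | str) -> GrowthModel:
    return GrowthModel(model)


def validate_params(model: GrowthModel | str, params: Sequence[float]) -> np.ndarray:
    """Check a parameter vector against the model's constraints.

    Returns the parameters as a float array; raises
    :class:`InvalidParameterError` naming the violated constraint otherwise.
    """
    model = _as_model(model)
    p = np.asarray(params, dtype=float)
    if p.shape != (3,):
        raise InvalidParameterError(
            f"{model.value} takes exactly 3 parameters, got shape {p.shape}"
        )
    if not np.all(np.isfinite(p)):
        raise InvalidParameterError(f"{model.value} parameters must be finite: {p}")
    a, b, c = p
    if model is GrowthModel.GOMPERTZ:
        if a <= 0:
            raise InvalidParameterError(f"gompertz requires a > 0, got a={a}")
        if b <= 0:
            raise InvalidParameterError(f"gompertz requires b > 0, got b={b}")
        if not (0 < c < 1):
            raise InvalidParameterError(f"gompertz requires 0 < c < 1, got c={c}")
    elif model is GrowthModel.RICHARD:
        if a <= 0 or b <= 0 or c <= 0:
            raise InvalidParameterError(
                f"richard requires a, b, c > 0, got (a={a}, b={b}, c={c})"
            )
    elif model is GrowthModel.LOGISTIC:
        asym, _xmid, scal = a, b, c
        if asym <= 0:
            raise InvalidParameterError(f"logistic requires Asym > 0, got Asym={asym}")
        if scal <= 0:
            raise InvalidParameterError(f"logistic requires scal > 0, got scal={scal}")
    elif model is GrowthModel.ASYMPTOTIC:
        if not (a > b >= 0):
            raise InvalidParameterError(
                f"asymptotic requires a > b >= 0, got (a={a}, b={b})"
            )
    return p


def eval_model(model: GrowthModel | str, params: Sequence[float], t) -> np.ndarray | float:
    """Evaluate the growth law y(t). Vectorized over `t` (years, t >= 0)."""
    model = _as_model(model)
    a, b, c = validate_params(model, params)
    tt = np.asarray(t, dtype=float)
    if model is GrowthModel.GOMPERTZ:
        y = a * np.exp(-b * np.power(c, tt))
    elif model is GrowthModel.RICHARD:
        y = a * np.power(1.0 - np.exp(-b * tt), c)
    elif model is GrowthModel.LOGISTIC:
        asym, xmid, scal = a, b, c
        y = asym / (1.0 + np.exp((xmid - tt) / scal))
    else:  # asymptotic
        y = a + (b - a) * np.exp(-np.exp(c) * tt)
    return y if y.ndim else float(y)


def eval_derivatives(
    model: GrowthModel | str, params: Sequence[float], t
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Analytic (dy/dt, d2y/dt2) of the growth law, vectorized over t.

    The Chapman-Richards law with c < 1 has a one-sided singularity at
    exactly t = 0 (dy/dt -> +inf); the returned values are +/-inf there,
    finite for all t > 0.
    """
    model = _as_model(model)
    a, b, c = validate_params(model, params)
    tt = np.asarray(t, dtype=float)
    if model is GrowthModel.GOMPERTZ:
        # y = a exp(-b c^t); y' = -a b ln(c) c^t exp(-b c^t) > 0 since ln c < 0
        ct = np.power(c, tt)
        e = np.exp(-b * ct)
        lnc = math.log(c)
        d1 = -a * b * lnc * ct * e
        d2 = -a * b * lnc**2 * ct * e * (1.0 - b * ct)
    elif model is GrowthModel.RICHARD:
        # y = a u^c with u = 1 - exp(-bt); y' = a c b e^{-bt} u^{c-1}
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ebt = np.exp(-b * tt)
            u = 1.0 - ebt
            d1 = a * c * b * ebt * np.power(u, c - 1.0)
            d2 = a * c * b**2 * ebt * np.power(u, c - 2.0) * ((c - 1.0) * ebt - u)
        # u = 0 at t = 0: limits depend on c (0 for c>2 etc.); keep inf/nan -> inf
        if np.any(u == 0):
            d1 = np.where(u == 0, _richard_d1_at_zero(a, b, c), d1)
            d2 = np.where(u == 0, _richard_d2_at_zero(a, b, c), d2)
    elif model is GrowthModel.LOGISTIC:
        asym, xmid, scal = a, b, c
        z = np.exp((xmid - tt) / scal)
        d1 = asym * z / (scal * (1.0 + z) ** 2)
        d2 = asym * z * (z - 1.0) / (scal**2 * (1.0 + z) ** 3)
    else:  # asymptotic
        k = math.exp(c)
        e = np.exp(-k * tt)
        d1 = (a - b) * k * e
        d2 = -(a - b) * k**2 * e
    if np.ndim(t) == 0:
        return float(d1), float(d2)
    return d1, d2


def _richard_d1_at_zero(a: float, b: float, c: float) -> float:
    # one-sided limit of a c b e^{-bt} (1-e^{-bt})^{c-1} as t -> 0+
    if c > 1:
        return 0.0
    if c == 1:
        return a * b
    return math.inf


def _richard_d2_at_zero(a: float, b: float, c: float) -> float:
    if c > 2:
        return 0.0
    if c == 2:
        return 2 * a * b**2
    if c == 1:
        return -a * b**2
    return math.inf if c > 1 else -math.inf


def time_of_max_growth(model: GrowthModel | str, params: Sequence[float]) -> float | None:
    """Time t* (years) at which the growth rate dy/dt is maximal.

    This is the interior inflection point solving d2y/dt2 = 0, available in
    closed form for every supported law:

    * logistic: t* = xmid
    * gompertz: t* = ln(b) / (-ln(c))
    * richard (c > 1): t* = ln(c) / b

    Returns ``None`` when the law has no interior inflection for these
    parameters (asymptotic always; richard with c <= 1), i.e. growth rate is
    maximal at t = 0.
    """
    model = _as_model(model)
    a, b, c = validate_params(model, params)
    if model is GrowthModel.LOGISTIC:
        return float(b)  # xmid
    if model is GrowthModel.GOMPERTZ:
        # d2 = 0 at b c^t = 1
        t = math.log(b) / (-math.log(c))
        return t if t > 0 else None
    if model is GrowthModel.RICHARD:
        if c <= 1:
            return None
        return math.log(c) / b
    return None  # asymptotic: pure decay of growth rate


def asymptote(model: GrowthModel | str, params: Sequence[float]) -> float:
    """Plateau value lim t->inf of the growth law (`a` or `Asym`)."""
    model = _as_model(model)
    if model is GrowthModel.GOMPERTZ and float(params[2]) >= 1:
        raise DivergentModelError("gompertz diverges for c >= 1; no asymptote")
    a, b, c = validate_params(model, params)
    if model is GrowthModel.LOGISTIC:
        return float(a)  # Asym
    return float(a)
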
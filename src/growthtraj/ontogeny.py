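"""Curvature-based ontogenetic staging of fitted growth trajectories.

A fitted growth curve is divided into two developmental phases -- rapid
growth and reduced growth -- at the point of maximum curvature

    kappa(t) = |y''(t)| / (1 + y'(t)^2)^(3/2)

on the decelerating limb of the curve (t past the inflection point, where the
growth rate is already falling). Curvature is not unit-invariant: it is
computed on raw trait/age units by default (height in m, DBH in cm, age in
years); ``normalize="minmax"`` rescales both axes to [0, 1] first for a
unit-free alternative.

The maximum is located by a dense grid scan (default step 0.01 y) followed by
deterministic golden-section refinement, so identical inputs give identical
phase boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .fitting import FitResult
from .growth_models import (
    GrowthModel,
    asymptote,
    eval_derivatives,
    eval_model,
    time_of_max_growth,
)

__all__ = [
    "CurvaturePoint",
    "curvature",
    "max_curvature_point",
    "phase_report",
    "plot_class_trajectories",
    "PHASE_LABELS",
]

PHASE_LABELS = ("rapid growth", "reduced growth")

#: grid step (years) of the coarse curvature scan
GRID_DT = 0.01


@dataclass(frozen=True)
class CurvaturePoint:
    """Location of the maximum-curvature point of a fitted trajectory."""

    t_mc: float  # years
    y_mc: float  # trait value at t_mc
    kappa: float  # curvature at t_mc
    search_window: tuple[float, float]
    on_boundary: bool  # argmax hit a window edge (no interior max)
    limb: str  # "decelerating" or "accelerating"


def curvature(
    model: GrowthModel | str,
    params: Sequence[float],
    t,
    normalize: str | None = None,
    window: tuple[float, float] | None = None,
):
    """Curvature kappa(t) of the growth curve, vectorized over t.

    With ``normalize="minmax"`` both axes are rescaled to [0, 1] over
    ``window`` (required in that mode) before computing kappa, removing the
    dependence on trait units.
    """
    d1, d2 = eval_derivatives(model, params, t)
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(~np.isfinite(d1)) or np.any(~np.isfinite(d2)):
        raise ValueError(
            f"singular derivative at t={t}: curvature undefined "
            "(Chapman-Richards with c < 1 is singular at t = 0)"
        )
    if normalize == "minmax":
        if window is None:
            raise ValueError("normalize='minmax' requires a window")
        t_lo, t_hi = window
        y_lo = float(eval_model(model, params, t_lo))
        y_hi = float(eval_model(model, params, t_hi))
        sx = t_hi - t_lo
        sy = max(y_hi - y_lo, 1e-12)
        # y_n(x) with x = (t - t_lo)/sx, y_n = (y - y_lo)/sy
        d1 = d1 * sx / sy
        d2 = d2 * sx**2 / sy
    elif normalize is not None:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    kappa = np.abs(d2) / (1.0 + d1**2) ** 1.5
    return kappa if kappa.ndim else float(kappa)


def max_curvature_point(
    model: GrowthModel | str,
    params: Sequence[float],
    window: tuple[float, float] | None = None,
    obs_span: float = 11.0,
    guard_decelerating: bool = True,
    normalize: str | None = None,
) -> CurvaturePoint:
    """Locate the maximum-curvature point used as the phase boundary.

    The default search window is [inflection time (or 0), 3 x obs_span]. When
    ``guard_decelerating`` is set (default) the search is restricted to the
    decelerating limb (t past the inflection); a window lying entirely before
    the inflection is evaluated as requested but flagged
    ``limb="accelerating"``. An argmax on a window edge is flagged
    ``on_boundary=True`` rather than silently returned as interior.
    """
    model = GrowthModel(model)
    t_star = time_of_max_growth(model, params)
    if window is None:
        window = (t_star if t_star is not None else 0.0, 3.0 * obs_span)
    t_lo, t_hi = float(window[0]), float(window[1])
    if not t_hi > t_lo:
        raise ValueError(f"empty search window {window}")

    limb = "decelerating"
    lo = t_lo
    if guard_decelerating and t_star is not None:
        if t_hi <= t_star:
            limb = "accelerating"  # caller asked for the rising-rate limb
        else:
            lo = max(t_lo, t_star)

    # avoid the t = 0 singularity of richard c < 1
    if model is GrowthModel.RICHARD and params[2] < 1 and lo == 0.0:
        lo = 1e-6

    norm_window = (lo, t_hi) if normalize == "minmax" else None

    def kap(tv):
        return curvature(model, params, tv, normalize=normalize, window=norm_window)

    grid = np.arange(lo, t_hi + GRID_DT / 2, GRID_DT)
    grid[-1] = min(grid[-1], t_hi)
    kg = np.asarray(kap(grid))
    i = int(np.argmax(kg))
    on_boundary = i == 0 or i == len(grid) - 1
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if b > a:
        res = minimize_scalar(
            lambda tv: -kap(float(tv)),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-6},
        )
        t_mc = float(res.x)
        if kap(t_mc) < kg[i]:  # refinement must never lose to the grid
            t_mc = float(grid[i])
    else:
        t_mc = float(grid[i])

    return CurvaturePoint(
        t_mc=t_mc,
        y_mc=float(eval_model(model, params, t_mc)),
        kappa=float(kap(t_mc)),
        search_window=(t_lo, t_hi),
        on_boundary=on_boundary,
        limb=limb,
    )


def phase_report(
    class_fits: Mapping[str, FitResult],
    obs_span: float = 11.0,
    guard_decelerating: bool = True,
    normalize: str | None = None,
):
    """Per-genotype-class staging table, ordered by phase-boundary time.

    One row per class: phase boundary t_mc (end of rapid growth / onset of
    reduced growth), trait value there, inflection time (time of maximum
    growth rate), asymptote, and an extrapolation flag when t_mc lies beyond
    the observation span. Rows are sorted by t_mc so the later-transitioning
    (longer-growing) classes come last; the qualitative relation "larger
    asymptote => later boundary" is reported via the columns, not asserted.
    """
    import pandas as pd

    rows = []
    for label, fit in class_fits.items():
        cp = max_curvature_point(
            fit.model,
            fit.params,
            obs_span=obs_span,
            guard_decelerating=guard_decelerating,
            normalize=normalize,
        )
        t_star = time_of_max_growth(fit.model, fit.params)
        rows.append(
            {
                "class": label,
                "model": fit.model.value,
                "t_mc": cp.t_mc,
                "y_mc": cp.y_mc,
                "kappa": cp.kappa,
                "t_max_growth": t_star if t_star is not None else np.nan,
                "asymptote": asymptote(fit.model, fit.params),
                "rapid_phase": f"[0, {cp.t_mc:.3f}]",
                "reduced_phase": f"({cp.t_mc:.3f}, inf)",
                "extrapolated": cp.t_mc > obs_span,
                "on_boundary": cp.on_boundary,
            }
        )
    return pd.DataFrame(rows).sort_values("t_mc").reset_index(drop=True)


def plot_class_trajectories(
    class_fits: Mapping[str, FitResult],
    obs_span: float = 11.0,
    t_max: float | None = None,
    ax=None,
):
    """Plot fitted per-class curves with t_mc and inflection marked."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t_max = t_max if t_max is not None else 3.0 * obs_span
    grid = np.linspace(0.01, t_max, 400)
    for label, fit in class_fits.items():
        (line,) = ax.plot(grid, fit.predict(grid), label=label)
        cp = max_curvature_point(fit.model, fit.params, obs_span=obs_span)
        ax.axvline(cp.t_mc, color=line.get_color(), ls="--", lw=0.8)
        t_star = time_of_max_growth(fit.model, fit.params)
        if t_star is not None:
            ax.axvline(t_star, color=line.get_color(), ls=":", lw=0.8)
    ax.axvspan(obs_span, t_max, alpha=0.08, color="grey", label="extrapolated")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("trait value")
    ax.legend(fontsize=8)
    return ax
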
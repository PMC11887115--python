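"""Locating the prevalence-peak trace on a gridded surface.

The trace a-hat(t) is the curve of ages where p(t, .) attains its interior
maximum (d p/d a = 0 with negative curvature).  Two routes are provided:

* per-year peak extraction from the grid, refined by a quadratic through
  the argmax node and its neighbours, and
* integration of the implicit-function-theorem ODE

      a'(t) = - (dF/dt) / (dF/da),   F := d p / d a,

  which propagates a point known to lie on the trace.  Both describe the
  same curve; their agreement is a consistency check used by the tests.

Surface derivatives use second-order central differences on the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import TraceExistenceError, ValidationError
from .rates import PrevalenceSurface

__all__ = [
    "TraceCurve",
    "extract_peak_trace",
    "implicit_trace_rhs",
    "integrate_trace",
    "refine_on_trace",
    "second_age_derivative",
]

#: relative threshold under which dF/da is treated as zero (the trace ODE
#: divides by it)
EXISTENCE_RTOL = 1e-12
#: on-trace tolerance for the start of the trace ODE, relative to max |p|
START_RTOL = 1e-6


@dataclass
class TraceCurve:
    """Sampled trace a-hat(t), optionally with pointwise confidence bounds."""

    t: np.ndarray
    a_hat: np.ndarray                      # NaN marks a missing value
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    source: str = "grid_extraction"        # | implicit_ode | polynomial_root
    status: str = "ok"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.a_hat = np.asarray(self.a_hat, float)
        if self.t.shape != self.a_hat.shape:
            raise ValidationError("t and a_hat must have equal shapes")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("t samples must be strictly increasing")
        for name in ("ci_low", "ci_high"):
            b = getattr(self, name)
            if b is not None:
                setattr(self, name, np.asarray(b, float))
        if self.ci_low is not None and self.ci_high is not None:
            ok = np.isfinite(self.a_hat) & np.isfinite(self.ci_low)
            if np.any(self.ci_low[ok] > self.a_hat[ok] + 1e-9) or np.any(
                self.a_hat[ok] > self.ci_high[ok] + 1e-9
            ):
                raise ValidationError("require ci_low <= a_hat <= ci_high")

    def interp(self, t):
        """Linear interpolation of a_hat at times t (NaN outside)."""
        ok = np.isfinite(self.a_hat)
        return np.interp(
            np.asarray(t, float), self.t[ok], self.a_hat[ok],
            left=np.nan, right=np.nan,
        )


def _quadratic_refine(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Vertex of the parabola through (x[k-1..k+1], y[k-1..k+1])."""
    x0, x1, x2 = x[k - 1], x[k], x[k + 1]
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    A = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    B = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if A >= 0:  # flat or non-concave triple: keep the node
        return float(x1)
    v = -B / (2 * A)
    return float(np.clip(v, x0, x2))


def extract_peak_trace(
    surface: PrevalenceSurface,
    age_window: Optional[Tuple[float, float]] = None,
) -> TraceCurve:
    """Per-year interior maximum of p(t, .), quadratically refined.

    Years whose maximum sits on the edge of the window, or whose profile is
    flat, are recorded as missing (NaN) with a warning, never extrapolated.
    """
    t_axis = surface.grid.t_axis
    a_axis = surface.grid.a_axis
    if age_window is None:
        lo, hi = a_axis[0], a_axis[-1]
    else:
        lo, hi = age_window
        if lo >= hi:
            raise ValidationError("age_window must satisfy a_min < a_max")
    mask = (a_axis >= lo) & (a_axis <= hi)
    if mask.sum() < 3:
        raise ValidationError("age_window must contain >= 3 age knots")
    a_sub = a_axis[mask]
    vals = surface.values[:, mask]

    a_hat = np.full(len(t_axis), np.nan)
    n_edge = n_flat = 0
    for j in range(len(t_axis)):
        col = vals[j]
        if np.ptp(col) < 1e-15:
            n_flat += 1
            continue
        k = int(np.argmax(col))
        if k == 0 or k == len(a_sub) - 1:
            n_edge += 1
            continue
        a_hat[j] = _quadratic_refine(a_sub, col, k)
    if n_flat:
        warnings.warn(f"{n_flat} year(s) with a flat age profile: no unique maximum")
    if n_edge:
        warnings.warn(f"{n_edge} year(s) with the maximum on the window edge: skipped")
    return TraceCurve(t_axis, a_hat, source="grid_extraction")


class _SurfaceDerivatives:
    """Cached central-difference derivative fields of a surface."""

    def __init__(self, surface: PrevalenceSurface):
        g = surface.grid
        p = surface.values
        self.grid = g
        # F = dp/da, then its t- and a-derivatives, and d2p/da2 = dF/da
        self.F = np.gradient(p, g.a_axis, axis=1, edge_order=2)
        self.Ft = np.gradient(self.F, g.t_axis, axis=0, edge_order=2)
        self.Fa = np.gradient(self.F, g.a_axis, axis=1, edge_order=2)
        self.max_absF = float(np.max(np.abs(self.F))) or 1.0
        axes = (g.t_axis, g.a_axis)
        self._F = RegularGridInterpolator(axes, self.F)
        self._Ft = RegularGridInterpolator(axes, self.Ft)
        self._Fa = RegularGridInterpolator(axes, self.Fa)

    def at(self, t, a):
        pt = np.array([[t, a]])
        return float(self._F(pt)[0]), float(self._Ft(pt)[0]), float(self._Fa(pt)[0])


_DERIV_CACHE: dict = {}


def _derivs(surface: PrevalenceSurface) -> _SurfaceDerivatives:
    key = id(surface)
    entry = _DERIV_CACHE.get(key)
    if entry is None or entry[0] is not surface.values:
        entry = (surface.values, _SurfaceDerivatives(surface))
        _DERIV_CACHE[key] = entry
    return entry[1]


def _check_margin(surface: PrevalenceSurface, t: float, a: float) -> None:
    g = surface.grid
    if not (
        g.t_axis[0] <= t <= g.t_axis[-1] and g.a_axis[0] <= a <= g.a_axis[-1]
    ):
        raise ValidationError(f"point (t={t}, a={a}) outside the surface grid")
    # central differences of a second derivative need a 2-cell margin
    if (
        t < g.t_axis[min(2, len(g.t_axis) - 1)] - 1e-9
        or t > g.t_axis[max(-3, -len(g.t_axis))] + 1e-9
        or a < g.a_axis[min(2, len(g.a_axis) - 1)] - 1e-9
        or a > g.a_axis[max(-3, -len(g.a_axis))] + 1e-9
    ):
        warnings.warn(
            f"(t={t}, a={a}) is within 2 cells of the grid edge; "
            "derivative estimates degrade there"
        )


def implicit_trace_rhs(t: float, a: float, surface: PrevalenceSurface) -> float:
    """Trace slope a'(t) = -(dF/dt)/(dF/da) with F = dp/da.

    Raises :class:`TraceExistenceError` when |dF/da| is below the existence
    threshold (the implicit function theorem requires dF/da != 0).
    """
    _check_margin(surface, t, a)
    d = _derivs(surface)
    _, Ft, Fa = d.at(t, a)
    if abs(Fa) < EXISTENCE_RTOL * d.max_absF:
        raise TraceExistenceError(
            f"trace existence condition violated at (t={t}, a={a}): "
            f"|dF/da|={abs(Fa):.3e}"
        )
    return -Ft / Fa


def refine_on_trace(surface: PrevalenceSurface, t: float, a_guess: float) -> float:
    """Polish an approximate peak age until dp/da vanishes at (t, a).

    Brackets the sign change of the interpolated F = dp/da within one grid
    cell of ``a_guess`` and solves by Brent's method.  Useful to turn a
    grid-extracted peak into a start point that satisfies the strict
    on-trace tolerance of :func:`integrate_trace`.
    """
    from scipy.optimize import brentq

    d = _derivs(surface)
    a_axis = surface.grid.a_axis
    da = surface.grid.da

    def F(a):
        return d.at(t, a)[0]

    for half_width in (da, 2 * da, 4 * da):
        lo = max(a_guess - half_width, a_axis[0])
        hi = min(a_guess + half_width, a_axis[-1])
        if F(lo) * F(hi) < 0:
            return float(brentq(F, lo, hi, xtol=1e-10))
    raise ValidationError(
        f"no sign change of dp/da near (t={t}, a={a_guess}); not a peak?"
    )


def integrate_trace(
    surface: PrevalenceSurface,
    t_start: float,
    a_start: float,
    t_end: float,
) -> TraceCurve:
    """Integrate the trace ODE from a point on the trace.

    Classical RK4 with fixed step equal to the t-grid spacing.  The start
    must satisfy |dp/da| <= tol (i.e. actually lie on the trace).  If the
    existence condition fails or the curve leaves the grid before t_end,
    integration stops early and the curve's ``status`` says so.
    """
    d = _derivs(surface)
    F0, _, _ = d.at(t_start, a_start)
    p_scale = float(np.max(np.abs(surface.values))) or 1.0
    if abs(F0) > START_RTOL * p_scale:
        raise ValidationError(
            f"start point (t={t_start}, a={a_start}) is not on the trace: "
            f"|dp/da| = {abs(F0):.3e} exceeds tolerance {START_RTOL * p_scale:.3e}"
        )
    g = surface.grid
    h = g.dt if t_end >= t_start else -g.dt
    n = int(round(abs(t_end - t_start) / g.dt))
    ts = [t_start]
    as_ = [a_start]
    status = "ok"
    t, a = t_start, a_start
    a_lo, a_hi = g.a_axis[0], g.a_axis[-1]
    for _ in range(n):
        try:
            k1 = implicit_trace_rhs(t, a, surface)
            k2 = implicit_trace_rhs(t + h / 2, np.clip(a + h / 2 * k1, a_lo, a_hi), surface)
            k3 = implicit_trace_rhs(t + h / 2, np.clip(a + h / 2 * k2, a_lo, a_hi), surface)
            k4 = implicit_trace_rhs(t + h, np.clip(a + h * k3, a_lo, a_hi), surface)
        except TraceExistenceError:
            status = "existence_condition_failed"
            break
        a_next = a + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not (a_lo <= a_next <= a_hi):
            status = "left_age_domain"
            break
        t, a = t + h, a_next
        ts.append(t)
        as_.append(a)
    ts = np.asarray(ts)
    as_ = np.asarray(as_)
    if h < 0:
        ts, as_ = ts[::-1], as_[::-1]
    return TraceCurve(ts, as_, source="implicit_ode", status=status)


def second_age_derivative(surface: PrevalenceSurface, t, a):
    """d2 p / d a2 by central differences, interpolated at (t, a)."""
    d = _derivs(surface)
    pts = np.stack(np.broadcast_arrays(np.asarray(t, float), np.asarray(a, float)), axis=-1)
    return d._Fa(pts)
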
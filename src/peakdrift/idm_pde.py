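"""Transport PDE of the illness-death model, solved along characteristics.

The prevalence p(t, a) of an irreversible chronic disease obeys

    (d/dt + d/da) p = (1 - p) * (i - p * dm),

with incidence i and excess mortality dm = m1 - m0.  Along the 45-degree
characteristics t = t0 + tau, a = a0 + tau of the Lexis plane the PDE
reduces to a scalar Riccati ODE in tau with the constant special solution
p == 1; p == 0 is an equilibrium whenever i == 0.  A surface solve traces
every grid node back to its boundary anchor and integrates the Riccati ODE
forward along the characteristic.
"""

from __future__ import annotations

from typing import Callable, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .errors import NumericalError, ValidationError
from .rates import LexisGrid, PrevalenceSurface, RateField

__all__ = ["characteristic_rhs", "solve_characteristic", "solve_surface"]

#: default tolerances of the adaptive Dormand-Prince integrator
RTOL = 1e-10
ATOL = 1e-12

BoundarySpec = Union[float, Callable[[np.ndarray], np.ndarray], None]


def characteristic_rhs(tau, p, rates: RateField, t0: float, a0: float):
    """Right-hand side (1-p)(i - p*dm) at the point (t0+tau, a0+tau).

    This is the Riccati ODE obtained by restricting the transport PDE to a
    characteristic.  ``p == 1`` is a fixed point for any rates.
    """
    t = t0 + tau
    a = a0 + tau
    i = np.asarray(rates.i(t, a), float)
    dm = np.asarray(rates.dm(t, a), float)
    for name, v in (("i", i), ("m0/m1 (dm)", dm)):
        if not np.all(np.isfinite(v)):
            raise ValidationError(
                f"rate field '{name}' is non-finite at (t={t}, a={a})"
            )
    return (1.0 - p) * (i - p * dm)


def solve_characteristic(
    rates: RateField,
    t0: float,
    a0: float,
    p0: float,
    tau_max: float,
    step: float,
    rtol: float = RTOL,
    atol: float = ATOL,
):
    """Integrate prevalence along the characteristic through (t0, a0).

    Returns ``(tau, p)`` with ``tau = 0, step, ..., tau_max`` and p clipped
    to [0, 1] on output (the integrator keeps it inside up to tolerance).
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    if tau_max < 0:
        raise ValidationError("tau_max must be non-negative")
    if not 0.0 <= p0 <= 1.0:
        raise ValidationError("p0 must lie in [0, 1]")
    n = int(round(tau_max / step))
    taus = np.linspace(0.0, tau_max, n + 1)
    if tau_max == 0.0:
        return taus, np.array([p0])
    sol = solve_ivp(
        characteristic_rhs,
        (0.0, tau_max),
        [p0],
        t_eval=taus,
        args=(rates, t0, a0),
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"characteristic integration failed: {sol.message}")
    p = sol.y[0]
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise NumericalError("prevalence left [0, 1] beyond solver tolerance")
    return taus, np.clip(p, 0.0, 1.0)


def _boundary_values(spec: BoundarySpec, x: np.ndarray, what: str) -> np.ndarray:
    if spec is None:
        raise ValidationError(f"boundary '{what}' is required but unspecified")
    vals = spec(x) if callable(spec) else np.full_like(x, float(spec))
    vals = np.asarray(vals, float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValidationError(f"boundary '{what}' values must lie in [0, 1]")
    return vals


def solve_surface(
    rates: RateField,
    grid: LexisGrid,
    boundary_age: BoundarySpec = 0.0,
    boundary_time: BoundarySpec = None,
    substep: Optional[float] = None,
) -> PrevalenceSurface:
    """Solve the transport PDE on a Lexis rectangle.

    Every grid node (t, a) is connected to the domain boundary by the
    characteristic through it; the node value is the Riccati solution
    integrated from the anchor.  ``boundary_age`` gives p at the lower age
    edge (default 0: no prevalence at the youngest age, e.g. no congenital
    disease when the grid starts at a = 0); ``boundary_time`` gives p along
    the initial year.  Nodes whose characteristic exits through the initial
    year require ``boundary_time``; if it is missing they are reported.

    All characteristics are integrated simultaneously with a fixed-step
    classical Runge-Kutta scheme on a normalised arc parameter; ``substep``
    (years, default half the finer grid spacing) controls accuracy.
    """
    t0g, a0g = grid.t_axis[0], grid.a_axis[0]
    tt, aa = grid.mesh()
    back_to_age = aa - a0g       # distance to the age edge along the characteristic
    back_to_time = tt - t0g
    needs_time_edge = back_to_time < back_to_age - 1e-12
    if boundary_time is None and np.any(needs_time_edge):
        nodes = np.argwhere(needs_time_edge)
        sample = [
            f"(t={grid.t_axis[j]:g}, a={grid.a_axis[k]:g})" for j, k in nodes[:5]
        ]
        raise ValidationError(
            "characteristic exits the domain through the initial year for "
            f"{len(nodes)} node(s) but no boundary_time was given; first: "
            + ", ".join(sample)
        )

    L = np.where(needs_time_edge, back_to_time, back_to_age)
    t_anchor = tt - L
    a_anchor = aa - L

    p = np.empty_like(L)
    p[~needs_time_edge] = _boundary_values(
        boundary_age, t_anchor[~needs_time_edge], "age edge"
    ) if np.any(~needs_time_edge) else 0.0
    if np.any(needs_time_edge):
        p[needs_time_edge] = _boundary_values(
            boundary_time, a_anchor[needs_time_edge], "time edge"
        )

    Lmax = float(L.max())
    if Lmax > 0.0:
        h = substep if substep is not None else 0.5 * min(grid.dt, grid.da)
        if h <= 0:
            raise ValidationError("substep must be positive")
        nsteps = max(1, int(np.ceil(Lmax / h)))

        def rhs(sigma, pv):
            # d p / d sigma = L * f(anchor + sigma L), sigma in [0, 1]
            t = t_anchor + sigma * L
            a = a_anchor + sigma * L
            i = np.asarray(rates.i(t, a), float)
            dm = np.asarray(rates.dm(t, a), float)
            return L * (1.0 - pv) * (i - pv * dm)

        hs = 1.0 / nsteps
        sigma = 0.0
        for _ in range(nsteps):
            k1 = rhs(sigma, p)
            k2 = rhs(sigma + 0.5 * hs, p + 0.5 * hs * k1)
            k3 = rhs(sigma + 0.5 * hs, p + 0.5 * hs * k2)
            k4 = rhs(sigma + hs, p + hs * k3)
            p = p + (hs / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            sigma += hs

    if not np.all(np.isfinite(p)):
        raise NumericalError("surface solve produced non-finite prevalence")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise NumericalError("surface solve left [0, 1] beyond tolerance")
    return PrevalenceSurface(grid, np.clip(p, 0.0, 1.0), provenance="pde_solution")
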
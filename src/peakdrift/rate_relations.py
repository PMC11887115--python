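"""Incidence / excess-mortality proportionality on the trace.

Differentiating the transport PDE with respect to age and using that
d p/d a vanishes on the trace gives

    d i/d a (t, a-hat) = p * d dm/d a (t, a-hat) + Pert(t, a-hat),

where the perturbation term

    Pert = 1/(1 - p) * d/da [(d/dt + d/da) p]          (surface form)
    Pert = p * d/da [(d/dt + d/da) f]                  (expit-polynomial form)

measures the deviation from exact proportionality.  When Pert is small the
age-related change in incidence on the trace is simply the age-related
change in excess mortality weighted by the prevalence — so prevalence data
plus excess-mortality trends suffice to project incidence trends.

The excess-mortality age slope never needs to be a fitted field here: it
enters linearly and may be passed as a plain number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np

from .errors import NumericalError, ValidationError
from .logistic_drift import LogisticPolyModel, expit_eval, trace_inverse
from .rates import PrevalenceSurface
from .trace_dynamics import TraceCurve, _derivs

__all__ = [
    "ProportionalityRow",
    "implied_incidence",
    "perturbation_pde",
    "perturbation_logistic",
    "incidence_slope_on_trace",
    "proportionality_table",
]

ON_TRACE_RTOL = 1e-6


@dataclass
class ProportionalityRow:
    """One row of the proportionality report: p(t_i, a_i) on the trace."""

    age: float
    t: float                     # NaN when the age is never attained
    prevalence: float
    extrapolated: bool

    def rounded(self) -> tuple:
        """Report view: integer year, two-decimal prevalence."""
        return (
            self.age,
            int(round(self.t)) if np.isfinite(self.t) else None,
            round(self.prevalence, 2) if np.isfinite(self.prevalence) else None,
        )


def implied_incidence(model: LogisticPolyModel, dm, m0=0.001):
    """The incidence field that makes an expit-polynomial an exact PDE solution.

    For any excess-mortality field dm there is an incidence

        i(t, a) = p(t, a) * ((d/dt + d/da) f(t, a) + dm(t, a)),

    such that p = expit(f) solves the illness-death transport PDE; this is
    what legitimises the expit-polynomial as a prevalence model.  Returns a
    :class:`~peakdrift.rates.RateField` (``m0`` is an arbitrary baseline
    mortality: prevalence only feels the excess ``dm``).  The implied i can
    be negative where the surface decays faster than dm removes cases —
    query :meth:`RateField.validate_at` over the intended domain to check.
    """
    from scipy.special import expit
    from .rates import RateField, _as_callable

    dm_fn = _as_callable(dm)
    m0_fn = _as_callable(m0)

    def i(t, a):
        p = expit(model.f(t, a))
        df = model.df_dt(t, a) + model.df_da(t, a)
        return p * (df + dm_fn(t, a))

    def m1(t, a):
        return m0_fn(t, a) + dm_fn(t, a)

    return RateField(i, m0_fn, m1, meta={"implied_from": "expit_polynomial"})


def perturbation_pde(surface: PrevalenceSurface, trace: TraceCurve) -> np.ndarray:
    """Pert(t, a-hat) from a gridded surface by central differences.

    Evaluated at each (t, a_hat) sample of the trace; requires interior
    points with p < 1 - 1e-6 (the division by 1 - p blows up otherwise).
    """
    d = _derivs(surface)
    out = np.full(len(trace.t), np.nan)
    interp_p = surface.interpolator()
    # d/da of the characteristic derivative: dFt + dFa with F = dp/da
    for j, (t, a) in enumerate(zip(trace.t, trace.a_hat)):
        if not np.isfinite(a):
            continue
        pt = np.array([[t, a]])
        p = float(interp_p(pt)[0])
        if p > 1 - 1e-6:
            raise NumericalError(
                f"Pert undefined at (t={t}, a={a}): p={p} too close to 1"
            )
        ft = float(d._Ft(pt)[0])
        fa = float(d._Fa(pt)[0])
        out[j] = (ft + fa) / (1.0 - p)
    return out


def perturbation_logistic(model: LogisticPolyModel, t, a) -> np.ndarray:
    """Pert for the expit-polynomial: d/da[(d/dt + d/da) f], closed form.

    In raw coefficients (deg_a = 3):
    beta1 + 2 a beta2 + 3 a^2 beta3 + 2(alpha2 + beta2 t) + 6 a (alpha3 + beta3 t);
    evaluated here in the conditioned basis with exact chain-rule factors.
    """
    s = np.asarray(t, float) - model.t_offset
    x = np.asarray(a, float) * model.a_scale
    beta = model.beta
    d_dt_part = beta[1] + 2 * x * beta[2]
    if model.deg_a == 3:
        d_dt_part = d_dt_part + 3 * x**2 * beta[3]
    return model.a_scale * d_dt_part + model.d2f_da2(t, a)


def _logistic_on_trace_check(model: LogisticPolyModel, t, a) -> None:
    slope = float(model.df_da(t, a))
    scale = max(abs(float(model.f(t, a))), 1.0)
    if abs(slope) > ON_TRACE_RTOL * scale:
        raise ValidationError(
            f"(t={t}, a={a}) is not on the trace: |df/da| = {abs(slope):.3e}"
        )


def incidence_slope_on_trace(
    source: Union[LogisticPolyModel, PrevalenceSurface],
    t: float,
    a: float,
    dm_slope: float,
) -> dict:
    """Age slope of incidence at an on-trace point (t, a).

    Returns the exact decomposition and its proportionality approximation:

    * ``slope``:  p * dm_slope + perturbation term,
    * ``approx``: p * dm_slope alone (valid when Pert is negligible),
    * ``pert``:   the perturbation term used,
    * ``p``:      the prevalence (the proportionality factor).

    ``dm_slope`` is d(dm)/da at (t, a) and may be symbolic in the sense of
    being any number supplied by the caller.
    """
    if not np.isfinite(dm_slope):
        raise ValidationError("dm_slope must be finite")
    if isinstance(source, LogisticPolyModel):
        _logistic_on_trace_check(source, t, a)
        p = float(expit_eval(source, t, a))
        pert = p * float(perturbation_logistic(source, t, a))
    else:
        d = _derivs(source)
        F, _, _ = d.at(t, a)
        p_scale = float(np.max(np.abs(source.values))) or 1.0
        if abs(F) > ON_TRACE_RTOL * p_scale:
            raise ValidationError(
                f"(t={t}, a={a}) is not on the trace: |dp/da| = {abs(F):.3e}"
            )
        # evaluate the surface Pert at this single point
        single = TraceCurve(np.array([t]), np.array([a]))
        pert = float(perturbation_pde(source, single)[0])
        p = float(source(t, a))
    slope = p * dm_slope + pert
    return {"slope": slope, "approx": p * dm_slope, "pert": pert, "p": p}


def proportionality_table(
    model: LogisticPolyModel,
    ages: Sequence[float],
) -> List[ProportionalityRow]:
    """Rows (a_i, t_i = trace inverse of a_i, p(t_i, a_i)) for given ages.

    Ages never attained by the trace yield a row with missing t and a
    warning.  Rows outside the observed years are flagged as extrapolated.
    Full precision is kept here; use :meth:`ProportionalityRow.rounded` for
    the report view (integer year, two-decimal prevalence).
    """
    rows: List[ProportionalityRow] = []
    for a in ages:
        try:
            t0 = trace_inverse(model, a)
        except NumericalError as exc:
            warnings.warn(f"age {a}: {exc}")
            rows.append(ProportionalityRow(float(a), np.nan, np.nan, False))
            continue
        p = float(expit_eval(model, t0, a))
        rows.append(
            ProportionalityRow(
                float(a), t0, p, bool(model.is_extrapolated(t0))
            )
        )
    return rows
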
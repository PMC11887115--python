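"""Synthetic study inputs: rate scenarios and aggregated-count data sets.

Everything the package consumes can be generated here without any
download: parametric incidence/mortality scenarios for the PDE route, and
binomial aggregated-count tables drawn from a known expit-polynomial truth
for the logistic route.  Every scenario records its ground truth (closed
form, true trace, or true coefficients) in metadata so tests never
re-derive it ad hoc, and all randomness flows through one seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .logistic_drift import AggregatedPrevalence, LogisticPolyModel
from .rates import RateField

__all__ = [
    "ScenarioSpec",
    "make_rate_scenario",
    "simulate_counts",
    "diabetes_like_truth",
    "SCENARIOS",
    "DIABETES_YEARS",
    "DIABETES_AGES",
    "DIABETES_TOTALS",
]

# -- diabetes-like truth ----------------------------------------------------
#
# A synthetic stand-in for a national male type 2 diabetes data set observed
# in 2009 and 2015 (the original aggregated file is not redistributable).
# The coefficients below, in the conditioned basis s = t - 2012, x = a/100,
# were calibrated once so that the expit-polynomial surface shows the
# canonical behaviour of that application: age profiles rising from ~2% at
# age 40 to a peak prevalence of ~0.33 in the high 70s, a peak drifting to
# older ages over calendar time, a trace inverse passing age 79 in mid-2012
# and age 80 around 2017, and far extrapolations reaching age 90 around
# 2067 at p ~ 0.83 and age 95 around 2090 at p ~ 0.94.  They are frozen:
# regenerating them is not part of any pipeline.
_DIABETES_COEF_CONDITIONED = np.array([
    -5.73095231,             # alpha0
    -9.42658719,             # alpha1  (x = a/100 basis)
    48.0288281,              # alpha2
    -35.5182722,             # alpha3
    0.0291224925,            # beta0   (s = t - 2012 basis)
    -0.0957797522,           # beta1
    0.109144414,             # beta2
    0.0270413242,            # beta3
])

DIABETES_T_OFFSET = 2012.0
DIABETES_A_SCALE = 0.01
DIABETES_YEARS = (2009.0, 2015.0)
DIABETES_AGES = np.arange(40.0, 101.0, 1.0)
DIABETES_TOTALS = 100_000


def diabetes_like_truth() -> LogisticPolyModel:
    """The canonical end-to-end fixture: a diabetes-like expit polynomial.

    Its surface peaks near age 78.4 in 2009, drifts upward by roughly a
    sixth of a year of age per calendar year over the observation window,
    and has peak prevalence ~0.33; the trace exists and is interior to
    ages 40-100 for all years of interest.
    """
    return LogisticPolyModel(
        _DIABETES_COEF_CONDITIONED.copy(),
        deg_a=3,
        deg_t=1,
        t_offset=DIABETES_T_OFFSET,
        a_scale=DIABETES_A_SCALE,
        years=np.asarray(DIABETES_YEARS),
        meta={"synthetic": True, "name": "diabetes_like"},
    )


@dataclass
class ScenarioSpec:
    """Recorded recipe for one synthetic data set."""

    name: str
    years: Sequence[float] = DIABETES_YEARS
    ages: Sequence[float] = field(default_factory=lambda: DIABETES_AGES.copy())
    totals: int = DIABETES_TOTALS
    seed: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.totals < 1:
            raise ValidationError("totals must be >= 1")
        if self.seed is None:
            raise ValidationError("a seed is mandatory")


# -- parametric rate scenarios (PDE route) ----------------------------------

def _constant_scenario() -> RateField:
    i0, m0c, m1c = 0.01, 0.01, 0.01
    meta = {
        "name": "constant",
        "i": i0, "m0": m0c, "m1": m1c, "dm": m1c - m0c,
        # with dm = 0 the characteristic solution is closed form
        "closed_form_p": lambda p0, tau: 1.0 - (1.0 - p0) * np.exp(-i0 * np.asarray(tau, float)),
    }
    return RateField.from_callables(i0, m0c, m1c, meta=meta)


def _age_exponential_scenario() -> RateField:
    # incidence rising exponentially with age, Gompertz-like excess
    # mortality overtaking it; the prevalence age profile then has a
    # unique interior maximum for every year (verified on solve in tests)
    ci, ki = 1e-3, 0.05
    cm, km = 2e-4, 0.085
    m0 = lambda t, a: 5e-5 * np.exp(0.09 * np.asarray(a, float)) + 0.0 * np.asarray(t, float)
    i = lambda t, a: ci * np.exp(ki * np.asarray(a, float)) + 0.0 * np.asarray(t, float)
    m1 = lambda t, a: m0(t, a) + cm * np.exp(km * np.asarray(a, float))
    meta = {
        "name": "age_exponential_incidence",
        "i": f"{ci}*exp({ki}*a)", "dm": f"{cm}*exp({km}*a)",
        "peak_age_window": (55.0, 95.0),
    }
    return RateField(i, m0, m1, meta=meta)


def _drifting_incidence_scenario() -> RateField:
    # secular incidence growth on top of the age-exponential shape; the
    # prevalence peak then drifts toward older ages over calendar time
    ci, ki, g = 1e-3, 0.05, 0.015
    cm, km = 2e-4, 0.085
    m0 = lambda t, a: 5e-5 * np.exp(0.09 * np.asarray(a, float)) + 0.0 * np.asarray(t, float)
    i = lambda t, a: ci * np.exp(
        ki * np.asarray(a, float) + g * (np.asarray(t, float) - 2000.0)
    )
    m1 = lambda t, a: m0(t, a) + cm * np.exp(km * np.asarray(a, float))
    meta = {
        "name": "drifting_incidence",
        "i": f"{ci}*exp({ki}*a + {g}*(t-2000))",
        "dm": f"{cm}*exp({km}*a)",
        "peak_age_window": (55.0, 95.0),
    }
    return RateField(i, m0, m1, meta=meta)


def _gompertz_gap_scenario() -> RateField:
    # constant incidence; the peak is carved out purely by the widening
    # Gompertz mortality gap between diseased and non-diseased
    i0 = 0.02
    cm, km = 1e-4, 0.11
    m0 = lambda t, a: 1e-4 * np.exp(0.09 * np.asarray(a, float)) + 0.0 * np.asarray(t, float)
    m1 = lambda t, a: m0(t, a) + cm * np.exp(km * np.asarray(a, float))
    meta = {
        "name": "gompertz_mortality_gap",
        "i": i0, "dm": f"{cm}*exp({km}*a)",
        "peak_age_window": (50.0, 100.0),
    }
    return RateField.from_callables(i0, m0, m1, meta=meta)


SCENARIOS = {
    "constant": _constant_scenario,
    "age_exponential_incidence": _age_exponential_scenario,
    "drifting_incidence": _drifting_incidence_scenario,
    "gompertz_mortality_gap": _gompertz_gap_scenario,
}


def make_rate_scenario(name: str) -> RateField:
    """Build a rate scenario from the closed catalogue.

    Available: constant, age_exponential_incidence, drifting_incidence,
    gompertz_mortality_gap.  Closed-form expressions are recorded in the
    returned field's ``meta``.
    """
    try:
        builder = SCENARIOS[name]
    except KeyError:
        raise ValidationError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    return builder()


# -- aggregated counts (logistic route) -------------------------------------

def simulate_counts(
    truth: LogisticPolyModel,
    years: Sequence[float] = DIABETES_YEARS,
    ages: Sequence[float] = DIABETES_AGES,
    totals: int = DIABETES_TOTALS,
    seed: int = 1,
    expected: bool = False,
) -> AggregatedPrevalence:
    """Draw an aggregated count table from an expit-polynomial truth.

    Per (year, age) cell: cases ~ Binomial(totals, expit(f*(t, a))),
    reproducible under ``seed``.  With ``expected=True`` the noise-free
    limit cases = round(totals * p) is returned instead (the seed is then
    irrelevant); this emulates an effectively infinite population.
    """
    if totals < 1:
        raise ValidationError("totals must be >= 1")
    years = np.asarray(years, float)
    ages = np.asarray(ages, float)
    tt, aa = np.meshgrid(years, ages, indexing="ij")
    t = tt.ravel()
    a = aa.ravel()
    p = expit(truth.f(t, a))
    n = np.full(p.shape, int(totals), dtype=np.int64)
    if expected:
        cases = np.round(n * p).astype(np.int64)
    else:
        if seed is None:
            raise ValidationError("a seed is mandatory for binomial simulation")
        rng = np.random.default_rng(seed)
        cases = rng.binomial(n, p)
    return AggregatedPrevalence(pd.DataFrame({
        "year": t, "age": a, "cases": cases, "total": n,
    }))
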
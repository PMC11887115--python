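"""Expit-polynomial prevalence model fitted to aggregated count data.

Aggregated prevalence data (per calendar year and age: number diseased,
number at risk) are modelled as

    p(t, a) = expit(f(t, a)),

with f a polynomial that is cubic (or quadratic) in age and linear in
calendar time,

    f(t, a) = sum_j alpha_j a^j  +  t * sum_j beta_j a^j,     j = 0..deg_a.

Any such surface is an exact solution of the illness-death transport PDE
for a suitable incidence field (see :mod:`peakdrift.rate_relations`), which
legitimises the expit-polynomial as a prevalence model.  Estimation is
binomial maximum likelihood (logistic regression with the canonical link)
on the count pairs; the age-profile peak — the prevalence-peak trace — then
has a closed form: d f/d a = 0 is a quadratic in age, and because f is
linear in t the trace inverse t(a) is available in closed form as well.

For numerical conditioning the design is built in centred/scaled
coordinates (t centred at the mean of the distinct years, age scaled by
1/100); every reported quantity is transformed back to raw years and ages
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import NumericalError, ValidationError
from .trace_dynamics import TraceCurve

__all__ = [
    "AggregatedPrevalence",
    "LogisticPolyModel",
    "design_row",
    "design_matrix",
    "expit_eval",
    "fit",
    "trace_roots",
    "trace_select",
    "trace_curve",
    "trace_inverse",
    "bootstrap",
    "BootstrapResult",
]

DEFAULT_AGE_WINDOW = (0.0, 120.0)
DEFAULT_A_SCALE = 0.01
DEFAULT_BOOTSTRAP_SEED = 20250307


@dataclass
class AggregatedPrevalence:
    """Rows of (year, age, cases, total) with derived observed prevalence.

    ``cases``/``total`` may be absent (prevalence-only mode, e.g. when a
    source publishes proportions without denominators); count-based
    estimation and bootstrap intervals are then unavailable.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        need = {"year", "age"}
        if missing := need - set(df.columns):
            raise ValidationError(f"aggregated data lacks columns {sorted(missing)}")
        if self.counts_available:
            bad = df.index[(df["cases"] < 0) | (df["cases"] > df["total"])]
            if len(bad):
                raise ValidationError(
                    f"cases outside [0, total] in row(s) {list(bad[:5])}"
                )
            if (df["total"] < 1).any():
                bad = df.index[df["total"] < 1]
                raise ValidationError(f"total < 1 in row(s) {list(bad[:5])}")
            df["prevalence"] = df["cases"] / df["total"]
        elif "prevalence" not in df.columns:
            raise ValidationError(
                "need either cases+total columns or a prevalence column"
            )
        dup = df.duplicated(subset=["year", "age"])
        if dup.any():
            raise ValidationError(
                f"duplicate (year, age) pairs in row(s) {list(df.index[dup][:5])}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def counts_available(self) -> bool:
        return {"cases", "total"} <= set(self.table.columns)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.table["year"].to_numpy(float))

    @property
    def ages(self) -> np.ndarray:
        return np.unique(self.table["age"].to_numpy(float))

    def __len__(self) -> int:
        return len(self.table)


def design_row(
    t: float,
    a: float,
    deg_a: int = 3,
    deg_t: int = 1,
    t_offset: float = 0.0,
    a_scale: float = 1.0,
) -> np.ndarray:
    """Feature vector (1, a, ..., a^deg_a, t, t*a, ..., t*a^deg_a).

    ``t`` is centred by ``t_offset`` and ``a`` multiplied by ``a_scale``
    before the powers are formed.
    """
    return design_matrix(
        np.array([t]), np.array([a]), deg_a, deg_t, t_offset, a_scale
    )[0]


def design_matrix(t, a, deg_a=3, deg_t=1, t_offset=0.0, a_scale=1.0) -> np.ndarray:
    if deg_a not in (2, 3):
        raise ValidationError(f"deg_a must be 2 or 3, got {deg_a}")
    if deg_t != 1:
        raise ValidationError(f"deg_t must be 1, got {deg_t}")
    s = np.asarray(t, float) - t_offset
    x = np.asarray(a, float) * a_scale
    age_block = np.stack([x**j for j in range(deg_a + 1)], axis=-1)
    return np.concatenate([age_block, s[..., None] * age_block], axis=-1)


@dataclass
class LogisticPolyModel:
    """Fitted (or constructed) expit-polynomial prevalence model.

    Coefficients are stored in the centred/scaled basis together with the
    centring constants, so evaluation in raw (year, age) coordinates is
    exact; :meth:`raw_coefficients` expands them to the raw basis.
    """

    coef: np.ndarray
    deg_a: int = 3
    deg_t: int = 1
    t_offset: float = 0.0
    a_scale: float = 1.0
    vcov: Optional[np.ndarray] = None
    years: Optional[np.ndarray] = None       # observed years (extrapolation flag)
    converged: bool = True
    ci_disabled: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, float)
        if self.coef.shape != (2 * (self.deg_a + 1),):
            raise ValidationError(
                f"expected {2 * (self.deg_a + 1)} coefficients, got {self.coef.shape}"
            )
        if self.vcov is not None:
            self.vcov = np.asarray(self.vcov, float)
            if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
                raise ValidationError("vcov must be symmetric")
        if self.years is not None:
            self.years = np.asarray(self.years, float)

    # -- evaluation ----------------------------------------------------
    @property
    def alpha(self) -> np.ndarray:
        return self.coef[: self.deg_a + 1]

    @property
    def beta(self) -> np.ndarray:
        return self.coef[self.deg_a + 1:]

    def f(self, t, a):
        """The polynomial f(t, a) on the logit scale."""
        X = design_matrix(t, a, self.deg_a, self.deg_t, self.t_offset, self.a_scale)
        return X @ self.coef

    def _xs(self, t, a):
        return np.asarray(t, float) - self.t_offset, np.asarray(a, float) * self.a_scale

    def df_da(self, t, a):
        s, x = self._xs(t, a)
        out = (self.alpha[1] + s * self.beta[1]) + 2 * x * (
            self.alpha[2] + s * self.beta[2]
        )
        if self.deg_a == 3:
            out = out + 3 * x**2 * (self.alpha[3] + s * self.beta[3])
        return self.a_scale * out

    def d2f_da2(self, t, a):
        s, x = self._xs(t, a)
        out = 2 * (self.alpha[2] + s * self.beta[2])
        if self.deg_a == 3:
            out = out + 6 * x * (self.alpha[3] + s * self.beta[3])
        return self.a_scale**2 * out

    def df_dt(self, t, a):
        _, x = self._xs(t, a)
        return sum(self.beta[j] * x**j for j in range(self.deg_a + 1))

    def raw_coefficients(self) -> dict:
        """Exact expansion to the raw basis (1, a, ..., t, t*a, ...)."""
        j = np.arange(self.deg_a + 1)
        raw_beta = self.beta * self.a_scale**j
        raw_alpha = (self.alpha - self.t_offset * self.beta) * self.a_scale**j
        return {"alpha": raw_alpha.tolist(), "beta": raw_beta.tolist()}

    @classmethod
    def from_raw_coefficients(cls, alpha, beta, t_offset=0.0,
                              a_scale=1.0, **kwargs) -> "LogisticPolyModel":
        alpha = np.asarray(alpha, float)
        beta = np.asarray(beta, float)
        deg_a = len(alpha) - 1
        j = np.arange(deg_a + 1)
        b = beta / a_scale**j
        a_ = alpha / a_scale**j + t_offset * b
        return cls(np.concatenate([a_, b]), deg_a=deg_a, t_offset=t_offset,
                   a_scale=a_scale, **kwargs)

    def is_extrapolated(self, t) -> np.ndarray:
        if self.years is None or len(self.years) == 0:
            return np.zeros(np.shape(t), bool)
        return (np.asarray(t, float) < self.years.min() - 1e-9) | (
            np.asarray(t, float) > self.years.max() + 1e-9
        )


def expit_eval(model: LogisticPolyModel, t, a):
    """Prevalence p(t, a) = expit(f(t, a)) in (0, 1); expit(0) = 0.5."""
    return expit(model.f(t, a))


def _rank_check(X: np.ndarray, names: Sequence[str]) -> None:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    deficient = diag < tol
    if deficient.any():
        cols = [names[piv[k]] for k in np.flatnonzero(deficient)]
        raise ValidationError(
            f"design matrix is rank deficient; collinear column(s): {cols}"
        )


def _column_names(deg_a: int) -> list:
    base = ["1"] + [f"a^{j}" if j > 1 else "a" for j in range(1, deg_a + 1)]
    return base + ["t"] + [f"t*{n}" for n in base[1:]]


def fit(
    data: AggregatedPrevalence,
    deg_a: int = 3,
    deg_t: int = 1,
    a_scale: float = DEFAULT_A_SCALE,
    method: str = "binomial",
) -> LogisticPolyModel:
    """Fit the expit-polynomial by binomial maximum likelihood.

    ``method="binomial"`` (default) maximises the binomial log-likelihood
    sum(cases * f - total * log(1 + exp(f))) via IRLS; the coefficient
    covariance is the observed-information inverse.  ``method="wls"`` is a
    least-squares fallback on logit(observed prevalence) with uniform
    weights for prevalence-only inputs; confidence intervals are then
    disabled.
    """
    df = data.table
    years = data.years
    if deg_t >= 1 and len(years) < 2:
        raise ValidationError("need >= 2 distinct years to fit a time trend")
    if len(data.ages) < deg_a + 2:
        raise ValidationError(f"need >= {deg_a + 2} distinct ages for deg_a={deg_a}")
    t_offset = float(years.mean())
    t = df["year"].to_numpy(float)
    a = df["age"].to_numpy(float)
    X = design_matrix(t, a, deg_a, deg_t, t_offset, a_scale)
    _rank_check(X, _column_names(deg_a))

    if method == "binomial":
        if not data.counts_available:
            raise ValidationError(
                "binomial fitting needs cases/total; use method='wls' for "
                "prevalence-only data"
            )
        cases = df["cases"].to_numpy(float)
        total = df["total"].to_numpy(float)
        try:
            res = sm.GLM(
                np.column_stack([cases, total - cases]), X,
                family=sm.families.Binomial(),
            ).fit()
        except Exception as exc:  # e.g. perfect separation
            raise NumericalError(f"binomial fit failed: {exc}") from exc
        if not res.converged:
            raise NumericalError(
                "binomial fit did not converge "
                f"(iterations={res.fit_history.get('iteration', '?')}, "
                f"last deviance={res.fit_history['deviance'][-1]:.6g})"
            )
        return LogisticPolyModel(
            res.params, deg_a=deg_a, deg_t=deg_t, t_offset=t_offset,
            a_scale=a_scale, vcov=np.asarray(res.cov_params()), years=years,
            converged=True,
            meta={"deviance": float(res.deviance), "method": "binomial",
                  "llf": float(res.llf), "n_obs": int(len(df))},
        )
    if method == "wls":
        prev = df["prevalence"].to_numpy(float)
        if np.any((prev <= 0) | (prev >= 1)):
            raise ValidationError("prevalence must lie strictly in (0, 1) for wls")
        y = np.log(prev / (1 - prev))
        res = sm.OLS(y, X).fit()
        return LogisticPolyModel(
            res.params, deg_a=deg_a, deg_t=deg_t, t_offset=t_offset,
            a_scale=a_scale, vcov=None, years=years, converged=True,
            ci_disabled=True, meta={"method": "wls", "n_obs": int(len(df))},
        )
    raise ValidationError(f"unknown fitting method {method!r}")


def trace_roots(model: LogisticPolyModel, t: float) -> np.ndarray:
    """Stationary ages of p(t, .): real roots of d f/d a = 0, ascending.

    For deg_a = 3 this is the quadratic
    (alpha1 + beta1 t) + 2 (alpha2 + beta2 t) a + 3 (alpha3 + beta3 t) a^2
    solved in numerically stable form; for deg_a = 2 a single linear root.
    A vanishing leading coefficient degrades to the linear root with a
    warning; complex roots give an empty set.
    """
    s = float(t) - model.t_offset
    c = model.alpha + s * model.beta
    if model.deg_a == 2:
        A, B = 0.0, 2 * c[2]
        C = c[1]
    else:
        A, B, C = 3 * c[3], 2 * c[2], c[1]
    scale = max(abs(A), abs(B), abs(C), 1e-300)
    if abs(A) < 1e-12 * scale:
        if model.deg_a == 3:
            warnings.warn(
                f"leading cubic coefficient vanishes at t={t}; "
                "falling back to the linear stationary point"
            )
        if abs(B) < 1e-300:
            return np.array([])
        roots_x = np.array([-C / B])
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return np.array([])
        sq = np.sqrt(disc)
        q = -(B + np.copysign(sq, B)) / 2
        roots_x = np.array([q / A, C / q]) if q != 0 else np.array([0.0, 0.0])
    return np.sort(roots_x / model.a_scale)


def trace_select(
    roots: np.ndarray,
    model: LogisticPolyModel,
    t: float,
    window=DEFAULT_AGE_WINDOW,
    prev_a_hat: Optional[float] = None,
) -> float:
    """Pick the plausible peak age among stationary candidates.

    Keeps roots inside the plausibility window (default ages 0-120, which
    discards e.g. negative ages) whose curvature marks a maximum; among
    several, prefers the largest prevalence, then proximity to the previous
    year's peak (continuity of the trace).  Returns NaN if none remain.
    """
    roots = np.asarray(roots, float)
    keep = [
        r for r in roots
        if window[0] <= r <= window[1] and model.d2f_da2(t, r) < 0
    ]
    if not keep:
        return np.nan
    if len(keep) == 1:
        return float(keep[0])
    ps = np.array([float(expit_eval(model, t, r)) for r in keep])
    best = np.flatnonzero(np.isclose(ps, ps.max(), rtol=1e-12, atol=1e-15))
    if len(best) > 1 and prev_a_hat is not None and np.isfinite(prev_a_hat):
        k = best[np.argmin(np.abs(np.asarray(keep)[best] - prev_a_hat))]
    else:
        k = best[0]
    return float(keep[k])


def trace_curve(
    model: LogisticPolyModel,
    t_values,
    window=DEFAULT_AGE_WINDOW,
) -> TraceCurve:
    """Analytic trace a-hat(t) sampled at t_values."""
    t_values = np.asarray(t_values, float)
    a_hat = np.full(t_values.shape, np.nan)
    prev = None
    for j, t in enumerate(t_values):
        a_hat[j] = trace_select(trace_roots(model, t), model, t, window, prev)
        if np.isfinite(a_hat[j]):
            prev = a_hat[j]
    return TraceCurve(
        t_values, a_hat, source="polynomial_root",
        meta={"extrapolated": model.is_extrapolated(t_values).tolist()},
    )


def trace_inverse(model: LogisticPolyModel, a0: float) -> float:
    """Calendar time t0 with (t0, a0) on the trace, i.e. a-hat(t0) = a0.

    Because f is linear in t, d f/d a (t, a0) = 0 is linear in t and t0 is
    obtained in closed form (no bracketing search is needed).  The solution
    must be a maximum of the age profile; a minimum means the age is never
    a prevalence peak.
    """
    x = float(a0) * model.a_scale
    j = np.arange(1, model.deg_a + 1)
    c1 = float(np.sum(j * model.alpha[1:] * x**(j - 1)))
    c2 = float(np.sum(j * model.beta[1:] * x**(j - 1)))
    if abs(c2) < 1e-300:
        raise NumericalError(
            f"age {a0} not attained by the trace: the stationarity condition "
            "does not depend on t there"
        )
    t0 = model.t_offset - c1 / c2
    if not model.d2f_da2(t0, a0) < 0:
        raise NumericalError(
            f"age {a0} not attained by the trace: the stationary point at "
            f"t={t0:.2f} is a minimum of the age profile"
        )
    return float(t0)


@dataclass
class BootstrapResult:
    """Percentile bands from parametric-binomial bootstrap refits."""

    raster: pd.DataFrame          # year, age, p_fit, p_low, p_high
    trace: TraceCurve             # a_hat with pointwise ci_low/ci_high
    B: int
    n_dropped: int
    seed: int


def bootstrap(
    data: AggregatedPrevalence,
    deg_a: int = 3,
    deg_t: int = 1,
    B: int = 1000,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    raster: Optional[pd.DataFrame] = None,
    trace_years: Optional[np.ndarray] = None,
    window=DEFAULT_AGE_WINDOW,
) -> BootstrapResult:
    """Pointwise 95% bands for prevalence and the trace.

    Parametric binomial bootstrap: each replicate resamples
    cases* ~ Binomial(total, p_fit) per cell and refits; bands are the
    2.5%/97.5% percentiles of the replicate prevalences on the (year, age)
    raster (default: the observed cells) and of the selected peak age per
    requested year.  Reproducible for a fixed seed.  Replicates that fail
    to converge are dropped; more than 10% dropped is an error.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if not data.counts_available:
        raise ValidationError("bootstrap needs cases/total counts")
    base = fit(data, deg_a=deg_a, deg_t=deg_t)
    df = data.table
    total = df["total"].to_numpy(float)
    p_fit_cells = np.asarray(
        expit_eval(base, df["year"].to_numpy(float), df["age"].to_numpy(float))
    )
    if raster is None:
        raster = df[["year", "age"]].copy()
    rt = raster["year"].to_numpy(float)
    ra = raster["age"].to_numpy(float)
    if trace_years is None:
        trace_years = data.years
    trace_years = np.asarray(trace_years, float)

    rng = np.random.default_rng(seed)
    prev_reps = np.empty((B, len(raster)))
    trace_reps = np.empty((B, len(trace_years)))
    n_dropped = 0
    kept = 0
    while kept < B:
        cases_star = rng.binomial(np.round(total).astype(np.int64), p_fit_cells)
        rep_df = df.copy()
        rep_df["cases"] = cases_star
        try:
            m = fit(AggregatedPrevalence(rep_df), deg_a=deg_a, deg_t=deg_t)
        except NumericalError:
            n_dropped += 1
            if n_dropped > 0.1 * B:
                raise NumericalError(
                    f"bootstrap: {n_dropped} non-converged replicates (> 10% of B={B})"
                )
            continue
        prev_reps[kept] = expit_eval(m, rt, ra)
        curve = trace_curve(m, trace_years, window=window)
        trace_reps[kept] = curve.a_hat
        kept += 1

    p_low, p_high = np.percentile(prev_reps, [2.5, 97.5], axis=0)
    out = raster.copy()
    out["p_fit"] = expit_eval(base, rt, ra)
    out["p_low"] = p_low
    out["p_high"] = p_high
    base_curve = trace_curve(base, trace_years, window=window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN replicates
        a_low, a_high = np.nanpercentile(trace_reps, [2.5, 97.5], axis=0)
    trace = TraceCurve(
        trace_years,
        base_curve.a_hat,
        ci_low=np.minimum(a_low, base_curve.a_hat),
        ci_high=np.maximum(a_high, base_curve.a_hat),
        source="polynomial_root",
    )
    return BootstrapResult(out, trace, B=B, n_dropped=n_dropped, seed=seed)
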
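"""Rate fields and gridded prevalence surfaces on the Lexis plane.

The Lexis plane is the (calendar time ``t``, age ``a``) coordinate plane of
demography.  Three transition rates of the irreversible illness-death model
live on it: the incidence ``i(t, a)`` (Non-diseased -> Diseased), and the
mortality rates ``m0(t, a)`` of the non-diseased and ``m1(t, a)`` of the
diseased, all per person-year.  The excess mortality ``dm = m1 - m0`` is
always derived, never stored, so the identity ``dm == m1 - m0`` holds
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import ValidationError

_log = logging.getLogger(__name__)

RateFunc = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _as_callable(value) -> RateFunc:
    """Promote a scalar to a constant field; pass callables through."""
    if callable(value):
        return value
    c = float(value)
    return lambda t, a: np.broadcast_arrays(np.full_like(np.asarray(t, float), c), a)[0]


@dataclass(frozen=True)
class RateField:
    """Incidence and mortality rates as functions of (t, a).

    The callables must be vectorised (accept equal-shaped arrays).  Rates are
    per person-year; time and age are continuous real numbers in years.
    """

    i: RateFunc
    m0: RateFunc
    m1: RateFunc
    meta: Mapping = field(default_factory=dict)

    def dm(self, t, a):
        """Excess mortality m1 - m0, computed on the fly."""
        return self.m1(t, a) - self.m0(t, a)

    def validate_at(self, t, a) -> None:
        """Check finiteness and sign of every rate at the given points."""
        t = np.asarray(t, float)
        a = np.asarray(a, float)
        for name in ("i", "m0", "m1"):
            vals = np.asarray(getattr(self, name)(t, a), float)
            if not np.all(np.isfinite(vals)):
                bad = np.argwhere(~np.isfinite(np.atleast_1d(vals)))[0]
                tb = np.atleast_1d(t)[tuple(bad)] if np.ndim(t) else t
                ab = np.atleast_1d(a)[tuple(bad)] if np.ndim(a) else a
                raise ValidationError(
                    f"rate field '{name}' is non-finite at (t={tb}, a={ab})"
                )
            if np.any(vals < 0):
                raise ValidationError(f"rate field '{name}' is negative")

    @classmethod
    def from_callables(cls, i, m0, m1, meta=None) -> "RateField":
        return cls(_as_callable(i), _as_callable(m0), _as_callable(m1),
                   meta=dict(meta or {}))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta=None) -> "RateField":
        """Build a bilinearly interpolated field from a long table.

        Expects columns ``t, a, i, m0, m1``; the (t, a) pairs must form a
        complete rectangular grid.  Queries outside the table are clamped to
        the nearest edge (a warning is logged once per field).
        """
        required = {"t", "a", "i", "m0", "m1"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"rate table lacks columns {sorted(missing)}")
        t_axis = np.unique(df["t"].to_numpy(float))
        a_axis = np.unique(df["a"].to_numpy(float))
        if len(df) != len(t_axis) * len(a_axis):
            raise ValidationError(
                "rate table is not a complete rectangular (t, a) grid"
            )
        wide = df.sort_values(["t", "a"])
        funcs = {}
        for name in ("i", "m0", "m1"):
            vals = wide[name].to_numpy(float).reshape(len(t_axis), len(a_axis))
            if np.any(vals < 0):
                raise ValidationError(f"rate table column '{name}' has negative values")
            interp = RegularGridInterpolator(
                (t_axis, a_axis), vals, method="linear",
                bounds_error=False, fill_value=None,
            )
            funcs[name] = _clamped(interp, t_axis, a_axis, name)
        return cls(funcs["i"], funcs["m0"], funcs["m1"], meta=dict(meta or {}))

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RateField":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)


def _clamped(interp, t_axis, a_axis, name) -> RateFunc:
    warned = [False]

    def f(t, a):
        t = np.asarray(t, float)
        a = np.asarray(a, float)
        out_of_range = (
            np.any(t < t_axis[0]) or np.any(t > t_axis[-1])
            or np.any(a < a_axis[0]) or np.any(a > a_axis[-1])
        )
        if out_of_range and not warned[0]:
            _log.warning(
                "rate field '%s': query outside table range; clamping to edge", name
            )
            warned[0] = True
        tc = np.clip(t, t_axis[0], t_axis[-1])
        ac = np.clip(a, a_axis[0], a_axis[-1])
        pts = np.stack(np.broadcast_arrays(tc, ac), axis=-1)
        return interp(pts)

    return f


# parametric rate families available from YAML configs -----------------------

def _family(spec: Mapping) -> RateFunc:
    kind = spec.get("family")
    if kind == "constant":
        return _as_callable(spec["value"])
    if kind == "exponential_age":
        c, k = float(spec["c"]), float(spec["k"])
        return lambda t, a: c * np.exp(k * np.asarray(a, float)) + 0.0 * np.asarray(t, float)
    if kind == "logistic_age":
        top = float(spec["top"]); mid = float(spec["mid"]); width = float(spec["width"])
        return lambda t, a: top / (1.0 + np.exp(-(np.asarray(a, float) - mid) / width)) + 0.0 * np.asarray(t, float)
    raise ValidationError(f"unknown rate family {kind!r}")


def rate_field_from_config(cfg: Mapping) -> RateField:
    """Build a RateField from a config mapping with keys i, m0, m1.

    Each entry is either a number (constant rate) or a mapping with a
    ``family`` key (constant, exponential_age, logistic_age).
    """
    funcs = {}
    for name in ("i", "m0", "m1"):
        if name not in cfg:
            raise ValidationError(f"rate config lacks entry '{name}'")
        spec = cfg[name]
        funcs[name] = _family(spec) if isinstance(spec, Mapping) else _as_callable(spec)
    return RateField(funcs["i"], funcs["m0"], funcs["m1"], meta={"config": dict(cfg)})


@dataclass(frozen=True)
class LexisGrid:
    """Rectangular discretisation of a Lexis rectangle."""

    t_axis: np.ndarray
    a_axis: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_axis, float)
        a = np.asarray(self.a_axis, float)
        object.__setattr__(self, "t_axis", t)
        object.__setattr__(self, "a_axis", a)
        for name, ax in (("t_axis", t), ("a_axis", a)):
            if ax.ndim != 1 or len(ax) < 2:
                raise ValidationError(f"{name} needs >= 2 knots")
            if np.any(np.diff(ax) <= 0):
                raise ValidationError(f"{name} must be strictly increasing")
        if a[0] < 0 or a[-1] > 120:
            raise ValidationError("a_axis must lie within [0, 120]")

    @classmethod
    def regular(cls, t0, t1, a0, a1, dt, da) -> "LexisGrid":
        if dt <= 0 or da <= 0:
            raise ValidationError("grid spacings must be positive")
        return cls(
            np.arange(t0, t1 + 0.5 * dt, dt),
            np.arange(a0, a1 + 0.5 * da, da),
        )

    @property
    def dt(self) -> float:
        return float(np.min(np.diff(self.t_axis)))

    @property
    def da(self) -> float:
        return float(np.min(np.diff(self.a_axis)))

    @property
    def uniform(self) -> bool:
        return (np.allclose(np.diff(self.t_axis), self.dt)
                and np.allclose(np.diff(self.a_axis), self.da))

    @property
    def shape(self):
        return len(self.t_axis), len(self.a_axis)

    def mesh(self):
        return np.meshgrid(self.t_axis, self.a_axis, indexing="ij")


@dataclass
class PrevalenceSurface:
    """Gridded prevalence p(t, a); values[j, k] = p(t_axis[j], a_axis[k])."""

    grid: LexisGrid
    values: np.ndarray
    provenance: str = "external"  # pde_solution | expit_polynomial | external

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != self.grid.shape:
            raise ValidationError(
                f"surface values shape {v.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("surface has non-finite values")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValidationError("surface values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.grid.t_axis, self.grid.a_axis), self.values, method="linear"
        )

    def __call__(self, t, a):
        pts = np.stack(np.broadcast_arrays(np.asarray(t, float), np.asarray(a, float)), axis=-1)
        return self.interpolator()(pts)

    def to_dataframe(self) -> pd.DataFrame:
        tt, aa = self.grid.mesh()
        return pd.DataFrame({
            "t": tt.ravel(), "a": aa.ravel(), "p": self.values.ravel()
        })
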
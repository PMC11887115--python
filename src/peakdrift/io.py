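"""Readers and writers for the package's tabular and JSON dialects.

Tables are long-format text (CSV or whitespace-delimited, auto-detected);
model files are versioned JSON.  All round-trips are lossless at stored
precision (floats are written with 17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .logistic_drift import AggregatedPrevalence, LogisticPolyModel
from .rates import LexisGrid, PrevalenceSurface
from .trace_dynamics import TraceCurve

__all__ = [
    "read_aggregated",
    "read_model", "write_model",
    "read_trace", "write_trace",
    "read_surface", "write_surface",
]

MODEL_SCHEMA = "peakdrift-model/1"
FLOAT_FMT = "%.17g"

#: accepted aliases for the required aggregated-data columns
COLUMN_ALIASES = {
    "year": {"year", "t", "calendar_year", "jahr"},
    "age": {"age", "a", "alter"},
    "cases": {"cases", "n_disease", "diseased", "n_cases", "k"},
    "total": {"total", "n_total", "at_risk", "n", "population"},
    "prevalence": {"prevalence", "prev", "p"},
    "sex": {"sex", "gender", "geschlecht"},
}


def _map_columns(df: pd.DataFrame, extra: Optional[Mapping] = None) -> pd.DataFrame:
    aliases = {k: set(v) for k, v in COLUMN_ALIASES.items()}
    for canon, names in (extra or {}).items():
        aliases.setdefault(canon, set()).update(
            {names} if isinstance(names, str) else names
        )
    rename = {}
    for col in df.columns:
        low = str(col).strip().lower()
        for canon, names in aliases.items():
            if low in names:
                rename[col] = canon
                break
    return df.rename(columns=rename)


def read_aggregated(
    path,
    column_aliases: Optional[Mapping] = None,
    sex: Optional[str] = None,
) -> AggregatedPrevalence:
    """Read an aggregated prevalence table (counts or prevalence-only).

    The delimiter (comma, tab or whitespace) is auto-detected and headers
    are matched case-insensitively against the alias table.  An optional
    ``sex`` value filters a sex column if one is present.  Validation
    failures are reported with 1-based data line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    df = _map_columns(df, column_aliases)
    if sex is not None:
        if "sex" not in df.columns:
            raise ValidationError("sex filter requested but no sex column found")
        df = df[df["sex"].astype(str).str.lower().str.startswith(str(sex).lower()[0])]
        df = df.drop(columns=["sex"]).reset_index(drop=True)
    elif "sex" in df.columns and df["sex"].nunique() > 1:
        raise ValidationError(
            "table mixes several sexes; pass a sex filter to select one"
        )

    have = set(df.columns)
    if not {"year", "age"} <= have:
        raise ValidationError(
            f"missing required columns: found {sorted(have)}, need year+age "
            "plus cases+total (or prevalence); accepted aliases: "
            + ", ".join(f"{k}={sorted(v)}" for k, v in COLUMN_ALIASES.items())
        )
    counts_mode = {"cases", "total"} <= have
    if not counts_mode and "prevalence" not in have:
        raise ValidationError(
            "need cases+total columns (or a prevalence column for the "
            f"prevalence-only fallback); found {sorted(have)}"
        )
    if counts_mode:
        bad = df.index[df["cases"] > df["total"]]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +1 header, +1 one-based
            raise ValidationError(f"cases > total on line(s) {lines}")
    cols = ["year", "age"] + (
        ["cases", "total"] if counts_mode else ["prevalence"]
    )
    return AggregatedPrevalence(df[cols].copy())


# -- model JSON -------------------------------------------------------------

def write_model(model: LogisticPolyModel, path) -> None:
    doc = {
        "schema": MODEL_SCHEMA,
        "deg_a": model.deg_a,
        "deg_t": model.deg_t,
        "t_offset": model.t_offset,
        "a_scale": model.a_scale,
        "coef_conditioned": model.coef.tolist(),
        "coef_raw": model.raw_coefficients(),
        "vcov": None if model.vcov is None else model.vcov.tolist(),
        "years": None if model.years is None else model.years.tolist(),
        "converged": model.converged,
        "ci_disabled": model.ci_disabled,
        "meta": {k: v for k, v in model.meta.items()
                 if isinstance(v, (str, int, float, bool, list))},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> LogisticPolyModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != MODEL_SCHEMA:
        raise ValidationError(
            f"unsupported model schema {doc.get('schema')!r}; expected {MODEL_SCHEMA}"
        )
    return LogisticPolyModel(
        np.asarray(doc["coef_conditioned"], float),
        deg_a=doc["deg_a"],
        deg_t=doc["deg_t"],
        t_offset=doc["t_offset"],
        a_scale=doc["a_scale"],
        vcov=None if doc["vcov"] is None else np.asarray(doc["vcov"], float),
        years=None if doc["years"] is None else np.asarray(doc["years"], float),
        converged=doc["converged"],
        ci_disabled=doc["ci_disabled"],
        meta=doc.get("meta", {}),
    )


# -- trace CSV --------------------------------------------------------------

def write_trace(trace: TraceCurve, path) -> None:
    df = pd.DataFrame({"t": trace.t, "a_hat": trace.a_hat})
    df["ci_low"] = trace.ci_low if trace.ci_low is not None else np.nan
    df["ci_high"] = trace.ci_high if trace.ci_high is not None else np.nan
    df["source"] = trace.source
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trace(path) -> TraceCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"t", "a_hat"}
    if missing := need - set(df.columns):
        raise ValidationError(f"trace file lacks columns {sorted(missing)}")
    ci_low = df["ci_low"].to_numpy(float) if "ci_low" in df else None
    ci_high = df["ci_high"].to_numpy(float) if "ci_high" in df else None
    if ci_low is not None and np.all(np.isnan(ci_low)):
        ci_low = ci_high = None
    source = str(df["source"].iloc[0]) if "source" in df else "grid_extraction"
    return TraceCurve(
        df["t"].to_numpy(float), df["a_hat"].to_numpy(float),
        ci_low=ci_low, ci_high=ci_high, source=source,
    )


# -- surface CSV ------------------------------------------------------------

def write_surface(surface: PrevalenceSurface, path) -> None:
    df = surface.to_dataframe()
    if df["p"].isna().any():
        raise ValidationError("surface contains NaN; refusing to write")
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_surface(path, provenance: str = "external") -> PrevalenceSurface:
    df = pd.read_csv(path, float_precision="round_trip")
    if missing := {"t", "a", "p"} - set(df.columns):
        raise ValidationError(f"surface file lacks columns {sorted(missing)}")
    t_axis = np.unique(df["t"].to_numpy(float))
    a_axis = np.unique(df["a"].to_numpy(float))
    if len(df) != len(t_axis) * len(a_axis):
        raise ValidationError("surface file is not a complete (t, a) grid")
    values = (
        df.sort_values(["t", "a"])["p"].to_numpy(float)
        .reshape(len(t_axis), len(a_axis))
    )
    return PrevalenceSurface(LexisGrid(t_axis, a_axis), values, provenance=provenance)
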
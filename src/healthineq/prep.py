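"""Reading, recoding and pooling of woman-level survey tables.

Covers the standard preparation steps for a pooled multi-round survey
analysis: constructing the four binary maternal-health-service outcomes from
their component fields, recoding "don't know"/missing covariate responses
into the least-advantaged category (keeping every woman in the denominator),
and pooling rounds with per-survey weight rescaling plus globally unique
stratum/cluster identifiers.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .synthetic import MISSING_SENTINEL

__all__ = [
    "OUTCOMES",
    "DEFAULT_COMPONENT_COLUMNS",
    "read_table",
    "read_stata",
    "build_outcomes",
    "recode_missing",
    "pool_and_rescale",
]

OUTCOMES = ("early_anc", "anc4plus", "quality_anc", "pnc2days")

#: canonical component-column names; readers may remap via ``mapping``
DEFAULT_COMPONENT_COLUMNS = {
    "skilled_anc": "skilled_anc",
    "anc_timing_months": "anc_timing_months",
    "anc_visits": "anc_visits",
    "bp_check": "bp_check",
    "blood_test": "blood_test",
    "urine_test": "urine_test",
    "skilled_pnc": "skilled_pnc",
    "pnc_timing_days": "pnc_timing_days",
}


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a comma-separated woman-level table (header row, UTF-8)."""
    return pd.read_csv(path, **kwargs)


def read_stata(path, **kwargs) -> pd.DataFrame:
    """Convenience reader for Stata-format files, the format DHS ships."""
    return pd.read_stata(path, **kwargs)


def _component(df: pd.DataFrame, mapping: Mapping[str, str], key: str) -> pd.Series:
    col = mapping.get(key, DEFAULT_COMPONENT_COLUMNS[key])
    if col not in df.columns:
        raise ConfigurationError(f"component column {col!r} ({key}) not in table")
    # nullable dtype so "not applicable" propagates through comparisons
    return pd.to_numeric(df[col], errors="coerce").astype("Float64")


def _binary_and(*conditions) -> pd.Series:
    """Conjunction with NA propagation: NA if any component is NA."""
    out = conditions[0].astype("boolean")
    for c in conditions[1:]:
        out = out & c.astype("boolean")
    return out.astype("Int64")


def build_outcomes(df: pd.DataFrame, mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Construct the four binary service outcomes from component fields.

    - ``early_anc``: skilled first antenatal visit begun in months 1-3 of
      pregnancy.
    - ``anc4plus``: at least four skilled antenatal visits.
    - ``quality_anc``: blood-pressure check AND blood test AND urine test all
      received (the three components recorded consistently across rounds).
    - ``pnc2days``: skilled postnatal contact within two days of delivery.

    Components that are not applicable (NA) yield NA outcomes; those rows are
    excluded per outcome downstream, never dropped globally.
    """
    mapping = dict(mapping or {})
    out = df.copy()

    timing = _component(df, mapping, "anc_timing_months")
    visits = _component(df, mapping, "anc_visits")
    pnc_days = _component(df, mapping, "pnc_timing_days")
    for name, series in (("anc_timing_months", timing), ("anc_visits", visits),
                         ("pnc_timing_days", pnc_days)):
        if (series.dropna() < 0).any():
            raise ValidationError(f"negative values in {name}")

    skilled_anc = _component(df, mapping, "skilled_anc")
    out["early_anc"] = _binary_and(skilled_anc == 1, (timing >= 1) & (timing <= 3))
    out["anc4plus"] = _binary_and(skilled_anc == 1, visits >= 4)
    out["quality_anc"] = _binary_and(
        _component(df, mapping, "bp_check") == 1,
        _component(df, mapping, "blood_test") == 1,
        _component(df, mapping, "urine_test") == 1,
    )
    out["pnc2days"] = _binary_and(
        _component(df, mapping, "skilled_pnc") == 1, pnc_days <= 2)
    return out


def recode_missing(
    df: pd.DataFrame,
    recode_map: Mapping[str, str],
    sentinel: str = MISSING_SENTINEL,
) -> pd.DataFrame:
    """Recode "don't know"/missing covariate values into the designated
    least-advantaged category (e.g. occupation -> "no occupation").

    Keeps every row: such responses stay in the denominator. Returns a copy;
    the number of rows never changes.
    """
    out = df.copy()
    for col, target in recode_map.items():
        if col not in out.columns:
            raise ConfigurationError(f"recode_map column {col!r} not in table")
        if target is None:
            raise ConfigurationError(f"no least-advantaged category declared for {col!r}")
        vals = out[col]
        mask = vals.isna() | (vals.astype(object) == sentinel)
        if mask.any():
            vals = vals.astype(object)
            vals[mask] = target
            out[col] = vals
    return out


def pool_and_rescale(
    tables,
    target_total: float = 1.0,
    weight: str = "weight",
    stratum: str = "stratum",
    cluster: str = "cluster",
    survey: str = "survey_year",
) -> pd.DataFrame:
    """Pool survey rounds so each counts equally, with unique design IDs.

    Accepts either a mapping ``{survey_label: table}`` or a single pooled
    table carrying a survey column. Adds three columns:

    - ``rescaled_weight``: original weight times ``target_total / (survey
      weight total)``, so every survey's weights sum to ``target_total``;
    - ``unique_stratum`` / ``unique_cluster``: survey label joined to the
      original IDs, so identical stratum or cluster names in different
      surveys never collide.

    Within a single survey the rescaling is a constant factor, leaving every
    rank-based and weighted-mean statistic unchanged.
    """
    if isinstance(tables, Mapping):
        frames = []
        for label, tab in tables.items():
            t = tab.copy()
            t[survey] = label
            frames.append(t)
        df = pd.concat(frames, ignore_index=True)
    else:
        df = tables.copy()
        if survey not in df.columns:
            raise ConfigurationError(f"survey column {survey!r} not in table")

    for col in (weight, stratum, cluster):
        if col not in df.columns:
            raise ConfigurationError(f"design column {col!r} not in table")
    w = pd.to_numeric(df[weight], errors="coerce")
    if w.isna().any() or (w <= 0).any():
        raise ValidationError("weights must be positive and non-missing")

    totals = w.groupby(df[survey]).transform("sum")
    if (totals <= 0).any():
        raise ValidationError("a survey has nonpositive total weight")
    df["rescaled_weight"] = w * (target_total / totals)
    sv = df[survey].astype(str)
    df["unique_stratum"] = sv + "|" + df[stratum].astype(str)
    df["unique_cluster"] = sv + "|" + df[cluster].astype(str)
    return df
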
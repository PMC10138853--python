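"""SWPER-style empowerment scoring and low/medium/high categorization.

Each empowerment domain (attitude to violence, social independence,
decision-making) is a linear score over survey items::

    score_d = sum_j loading_dj * (item_j - center_j) / scale_j

with principal-component loadings, centering/scaling constants, and two
cutpoints per domain mapping scores to ordinal low/medium/high categories.
Loadings are consumed as configuration, never re-estimated here: the shipped
``data/swper_synthetic_weights.yaml`` asset is a synthetic example with the
standard 14 item names, into which published SWPER Global values can be
pasted verbatim.

Boundary convention: a score equal to a cutpoint promotes (``score >= c``
yields the higher category).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "DomainWeights",
    "SwperWeights",
    "load_swper_weights",
    "synthetic_swper_weights_path",
    "score_domains",
    "categorize",
    "EMPOWERMENT_LEVELS",
]

EMPOWERMENT_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class DomainWeights:
    """Item loadings, centering/scaling constants, cutpoints, and optional
    coded item ranges for one empowerment domain."""

    loadings: Mapping[str, float]
    centers: Mapping[str, float]
    scales: Mapping[str, float]
    cutpoints: tuple[float, float]
    item_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        if not self.loadings:
            raise ConfigurationError(f"{name}: no item loadings")
        c1, c2 = self.cutpoints
        if not c1 < c2:
            raise ConfigurationError(f"{name}: cutpoints must be strictly increasing")
        for item in self.loadings:
            if self.scales.get(item, 1.0) == 0:
                raise ConfigurationError(f"{name}: zero scale for item {item!r}")


@dataclass(frozen=True)
class SwperWeights:
    """Per-domain scoring weights; the canonical configuration carries exactly
    14 loadings per domain (the DHS-available SWPER items)."""

    domains: Mapping[str, DomainWeights]

    def validate(self, require_14_items: bool = False) -> None:
        if not self.domains:
            raise ConfigurationError("no domains configured")
        for name, dw in self.domains.items():
            dw.validate(name)
            if require_14_items and len(dw.loadings) != 14:
                raise ConfigurationError(
                    f"{name}: canonical configuration requires exactly 14 "
                    f"item loadings, found {len(dw.loadings)}"
                )


def load_swper_weights(path, require_14_items: bool = True) -> SwperWeights:
    """Load a declarative YAML weight file keyed by domain and item name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    domains = {}
    for name, block in raw["domains"].items():
        loadings = {k: float(v) for k, v in block["loadings"].items()}
        domains[name] = DomainWeights(
            loadings=loadings,
            centers={k: float(v) for k, v in block.get("centers", {}).items()},
            scales={k: float(v) for k, v in block.get("scales", {}).items()},
            cutpoints=tuple(float(c) for c in block["cutpoints"]),
            item_ranges={k: (float(v[0]), float(v[1]))
                         for k, v in block.get("item_ranges", {}).items()},
        )
    weights = SwperWeights(domains=domains)
    weights.validate(require_14_items=require_14_items)
    return weights


def synthetic_swper_weights_path() -> str:
    """Path of the bundled synthetic example weight configuration."""
    return str(resources.files("healthineq.data") / "swper_synthetic_weights.yaml")


def categorize(score, cutpoints: Sequence[float]):
    """Map scores to ordinal low/medium/high via two increasing cutpoints.

    ``score < c1`` is low; ``c1 <= score < c2`` medium; ``score >= c2`` high
    (equality promotes).
    """
    c1, c2 = cutpoints
    if not c1 < c2:
        raise ConfigurationError("cutpoints must be strictly increasing")
    arr = np.asarray(score, dtype=float)
    idx = (arr >= c1).astype(int) + (arr >= c2).astype(int)
    cats = np.asarray(EMPOWERMENT_LEVELS, dtype=object)[idx]
    if arr.ndim == 0:
        return str(cats)
    return pd.Categorical(cats, categories=list(EMPOWERMENT_LEVELS), ordered=True)


def score_domains(
    items: pd.DataFrame,
    weights: SwperWeights,
) -> pd.DataFrame:
    """Score every configured domain for each woman and categorize.

    Returns a frame with ``<domain>_score`` and ``<domain>_category`` columns.
    Items listed in a domain's loadings must be present; values outside a
    configured coded range raise a validation error. Rows with missing items
    (e.g. a domain absent from one survey round) yield NA score and category.
    """
    weights.validate()
    out = pd.DataFrame(index=items.index)
    for name, dw in weights.domains.items():
        score = np.zeros(len(items), dtype=float)
        anymissing = np.zeros(len(items), dtype=bool)
        for item, loading in dw.loadings.items():
            if item not in items.columns:
                raise ConfigurationError(f"{name}: item column {item!r} missing")
            vals = pd.to_numeric(items[item], errors="coerce")
            rng = dw.item_ranges.get(item)
            if rng is not None:
                bad = vals.dropna()
                if ((bad < rng[0]) | (bad > rng[1])).any():
                    raise ValidationError(
                        f"{name}: item {item!r} outside coded range {rng}")
            anymissing |= vals.isna().to_numpy()
            center = dw.centers.get(item, 0.0)
            scale = dw.scales.get(item, 1.0)
            score += loading * (vals.fillna(0.0).to_numpy() - center) / scale
        score_s = pd.Series(score, index=items.index)
        score_s[anymissing] = np.nan
        out[f"{name}_score"] = score_s
        cat = pd.Series(
            categorize(score_s.fillna(dw.cutpoints[0]), dw.cutpoints),
            index=items.index,
        )
        cat[anymissing] = pd.NA
        out[f"{name}_category"] = cat
    return out
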
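"""Weighted fractional ranks, concentration indices, and concentration curves.

The concentration index (CI) of a health variable ``h`` with respect to a
socioeconomic ranking ``r`` is ``CI = (2/mu) * cov_w(h, r)``, where ``mu`` is
the weighted mean of ``h`` and ``cov_w`` the weighted covariance.  It equals
twice the area between the concentration curve and the line of equality, is
bounded in [-1, 1], and is positive when the outcome is concentrated among the
higher-ranked (advantaged) groups.

For a binary outcome the standard CI has range problems, so the Erreygers
normalized concentration index is used::

    ECI = 4 * mu * CI / (y_max - y_min)    # range 1 for binary h
        = 8 * cov_w(h, r)

ECI satisfies the mirror property: ``ECI(1 - h) = -ECI(h)`` exactly.

Ranks are weighted fractional ranks with category-midpoint tie handling: every
member of ordinal category ``c`` with weighted share ``w_c`` and cumulative
share ``W_c`` below it receives ``r = W_c + w_c / 2``.  The weighted mean rank
is exactly one half.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateRankingError,
    DesignError,
    UndefinedIndexError,
    ValidationError,
)

__all__ = [
    "RankedSample",
    "ConcentrationResult",
    "CurveCoordinates",
    "fractional_rank",
    "concentration_index",
    "erreygers_index",
    "eci_uncertainty",
    "erreygers_result",
    "concentration_curve",
]


@dataclass(frozen=True)
class RankedSample:
    """Normalized weights and tie-aware weighted fractional ranks.

    Attributes
    ----------
    rank : per-woman fractional rank in (0, 1); constant within a tied
        stratifier category and nondecreasing with category.
    weight : normalized sampling weights summing to one.
    category_code : integer code of the stratifier category (ascending order).
    categories : the ordered category labels.
    """

    rank: np.ndarray
    weight: np.ndarray
    category_code: np.ndarray
    categories: tuple

    @property
    def n(self) -> int:
        return self.rank.shape[0]

    @property
    def rank_variance(self) -> float:
        """Weighted variance of the rank variable."""
        rbar = float(self.weight @ self.rank)
        return float(self.weight @ (self.rank - rbar) ** 2)


@dataclass(frozen=True)
class ConcentrationResult:
    """Prevalence, standard CI, Erreygers index and its uncertainty."""

    prevalence: float
    ci_standard: float
    eci: float
    se: float
    ci95: tuple[float, float]
    n: int
    method: str
    outcome_range: float = 1.0

    def to_dict(self) -> dict:
        return {
            "prevalence": self.prevalence,
            "ci_standard": self.ci_standard,
            "eci": self.eci,
            "se": self.se,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "n": self.n,
            "method": self.method,
        }


@dataclass(frozen=True)
class CurveCoordinates:
    """Concentration-curve vertices: cumulative population share ``p`` versus
    cumulative weighted outcome share ``L(p)``, piecewise linear between
    category boundaries."""

    p: np.ndarray
    L: np.ndarray

    def interpolate(self, grid: Sequence[float]) -> np.ndarray:
        """L evaluated on an arbitrary grid in [0, 1]."""
        return np.interp(np.asarray(grid, dtype=float), self.p, self.L)

    def plot(self, ax=None, label: str | None = None):
        """Draw the curve and the line of equality; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot([0, 1], [0, 1], color="grey", lw=1, ls="--")
        ax.plot(self.p, self.L, lw=1.6, label=label)
        ax.set_xlabel("cumulative population share (ranked low to high)")
        ax.set_ylabel("C(p): cumulative outcome share")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        if label:
            ax.legend(frameon=False, fontsize=8)
        return ax


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if np.isnan(arr).any():
        raise ValidationError(f"{name} contains missing values")
    return arr


def fractional_rank(
    stratifier,
    weights,
    order: Sequence | None = None,
) -> RankedSample:
    """Weighted fractional ranks on an ordinal stratifier with midpoint ties.

    Parameters
    ----------
    stratifier : array-like of category labels (or an ordered pandas
        Categorical, whose order is respected).
    weights : positive sampling weights; normalized internally, so any
        rescaling of all weights leaves the ranks unchanged.
    order : explicit ascending category order (lowest = most disadvantaged).
        Required when labels do not sort meaningfully on their own.
    """
    w = _as_float_array(weights, "weights")
    if (w <= 0).any():
        raise ValidationError("weights must be strictly positive")

    s = pd.Series(stratifier)
    if order is not None:
        cat = pd.Categorical(s, categories=list(order), ordered=True)
    elif isinstance(s.dtype, pd.CategoricalDtype) and s.cat.ordered:
        cat = pd.Categorical(s, categories=list(s.cat.categories), ordered=True)
    else:
        cat = pd.Categorical(s, categories=sorted(pd.unique(s.dropna())), ordered=True)
    codes = np.asarray(cat.codes)
    if (codes < 0).any():
        raise ValidationError("stratifier contains values outside the declared order")
    if len(codes) != len(w):
        raise ValidationError("stratifier and weights have different lengths")

    if np.unique(codes).size < 2:
        raise DegenerateRankingError(
            "stratifier has a single observed category; ranking is degenerate "
            "and the concentration index is undefined"
        )

    w = w / w.sum()
    n_cat = len(cat.categories)
    share = np.bincount(codes, weights=w, minlength=n_cat)
    below = np.cumsum(share) - share
    rank_of_cat = below + share / 2.0
    return RankedSample(
        rank=rank_of_cat[codes],
        weight=w,
        category_code=codes,
        categories=tuple(cat.categories),
    )


def _weighted_cov(h: np.ndarray, ranked: RankedSample) -> float:
    w, r = ranked.weight, ranked.rank
    hbar = float(w @ h)
    rbar = float(w @ r)
    return float(w @ ((h - hbar) * (r - rbar)))


def concentration_index(h, ranked: RankedSample) -> float:
    """Standard concentration index ``(2/mu) * cov_w(h, r)``.

    ``h`` may be binary or any nonnegative health variable; its weighted mean
    must be positive.
    """
    harr = _as_float_array(h, "h")
    if len(harr) != ranked.n:
        raise ValidationError("h and ranked sample have different lengths")
    if (harr < 0).any():
        raise ValidationError("h must be nonnegative")
    mu = float(ranked.weight @ harr)
    if mu == 0:
        raise UndefinedIndexError("mean of h is zero; concentration index undefined")
    return 2.0 * _weighted_cov(harr, ranked) / mu


def _check_binary(harr: np.ndarray) -> None:
    if not np.isin(harr, (0.0, 1.0)).all():
        raise ValidationError(
            "Erreygers normalization applies to binary outcomes only; "
            "use concentration_index for ratio-scale variables"
        )


def erreygers_index(h, ranked: RankedSample) -> float:
    """Erreygers normalized concentration index for a binary outcome.

    ``ECI = 4 * mu * CI = 8 * cov_w(h, r)``; positive values mean the outcome
    is concentrated among the higher (advantaged) stratifier categories.
    """
    harr = _as_float_array(h, "h")
    if len(harr) != ranked.n:
        raise ValidationError("h and ranked sample have different lengths")
    _check_binary(harr)
    # symmetrized form: averaging the attainment and negated shortfall
    # covariances makes the mirror identity ECI(1-h) == -ECI(h) hold exactly
    # in floating point (the two differ only by rounding, ~1 ulp)
    return 4.0 * (_weighted_cov(harr, ranked) - _weighted_cov(1.0 - harr, ranked))


def _linearized(
    harr: np.ndarray,
    ranked: RankedSample,
    cluster: np.ndarray | None,
) -> tuple[float, float]:
    """Convenient-regression slope and its (cluster-)robust SE, scaled to ECI.

    The weighted slope of h on r equals cov_w(h, r) / var_w(r), so
    8 * var_w(r) * slope reproduces the covariance-formula ECI exactly; the SE
    is the robust SE of the slope scaled by the same factor.
    """
    import statsmodels.api as sm

    var_r = ranked.rank_variance
    if np.ptp(harr) == 0:  # degenerate: h constant, point mass at 0
        return 8.0 * _weighted_cov(harr, ranked), 0.0
    X = sm.add_constant(ranked.rank)
    model = sm.WLS(harr, X, weights=ranked.weight)
    if cluster is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": cluster})
    else:
        fit = model.fit(cov_type="HC1")
    eci = 8.0 * var_r * float(fit.params[1])
    se = 8.0 * var_r * float(fit.bse[1])
    return eci, se


def _stratified_cluster_bootstrap(
    harr: np.ndarray,
    ranked: RankedSample,
    cluster: np.ndarray,
    stratum: np.ndarray | None,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[float, tuple[float, float]]:
    if stratum is None:
        stratum = np.zeros(len(harr), dtype=int)
    df = pd.DataFrame({"stratum": stratum, "cluster": cluster})
    groups = df.groupby(["stratum", "cluster"], sort=True).indices
    by_stratum: dict = {}
    for (st, _cl), idx in groups.items():
        by_stratum.setdefault(st, []).append(np.asarray(idx))
    for st, clusters in by_stratum.items():
        if len(clusters) < 2:
            raise DesignError(
                f"stratum {st!r} has a single cluster; the stratified cluster "
                "bootstrap needs at least two clusters per stratum"
            )
    raw_w = ranked.weight
    labels = np.asarray(pd.Series(ranked.category_code))
    cats = ranked.categories
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        pieces = []
        for clusters in by_stratum.values():
            take = rng.integers(0, len(clusters), size=len(clusters))
            pieces.extend(clusters[t] for t in take)
        idx = np.concatenate(pieces)
        # ranks must be recomputed on the resample
        codes_b = labels[idx]
        if np.unique(codes_b).size < 2:
            estimates[b] = np.nan
            continue
        rk = fractional_rank(
            pd.Categorical.from_codes(codes_b, categories=list(cats), ordered=True),
            raw_w[idx],
        )
        estimates[b] = erreygers_index(harr[idx], rk)
    est = estimates[~np.isnan(estimates)]
    lo, hi = np.percentile(est, [2.5, 97.5])
    return float(est.std(ddof=1)), (float(lo), float(hi))


def eci_uncertainty(
    h,
    ranked: RankedSample,
    cluster=None,
    stratum=None,
    method: str = "linearized",
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Standard error and 95% interval for the Erreygers index.

    ``method='linearized'`` (default) uses the cluster-robust variance of the
    convenient-regression slope; ``method='bootstrap'`` resamples clusters
    with replacement within strata and takes percentile bounds.
    """
    harr = _as_float_array(h, "h")
    _check_binary(harr)
    point = erreygers_index(harr, ranked)
    cl = None if cluster is None else np.asarray(cluster)
    if method == "linearized":
        _, se = _linearized(harr, ranked, cl)
        ci95 = (point - 1.959963984540054 * se, point + 1.959963984540054 * se)
        return se, ci95
    if method == "bootstrap":
        if cl is None:
            raise DesignError("bootstrap requires cluster identifiers")
        rng = np.random.default_rng(seed)
        st = None if stratum is None else np.asarray(stratum)
        se, ci95 = _stratified_cluster_bootstrap(harr, ranked, cl, st, n_boot, rng)
        return se, ci95
    raise ValueError(f"unknown uncertainty method {method!r}")


def erreygers_result(
    h,
    ranked: RankedSample,
    cluster=None,
    stratum=None,
    method: str = "linearized",
    n_boot: int = 1000,
    seed: int | None = None,
) -> ConcentrationResult:
    """Full Erreygers analysis of a binary outcome: prevalence, standard CI,
    ECI, and design-based uncertainty."""
    harr = _as_float_array(h, "h")
    _check_binary(harr)
    mu = float(ranked.weight @ harr)
    if mu == 0:
        raise UndefinedIndexError("prevalence is zero; indices undefined")
    eci = erreygers_index(harr, ranked)
    se, ci95 = eci_uncertainty(
        harr, ranked, cluster=cluster, stratum=stratum, method=method,
        n_boot=n_boot, seed=seed,
    )
    return ConcentrationResult(
        prevalence=mu,
        ci_standard=eci / (4.0 * mu),
        eci=eci,
        se=se,
        ci95=ci95,
        n=ranked.n,
        method=method,
    )


def concentration_curve(h, ranked: RankedSample) -> CurveCoordinates:
    """Concentration-curve vertices at cumulative category boundaries.

    The curve lies below the diagonal when the outcome is concentrated among
    higher-ranked categories (positive index side); twice the signed area
    between the diagonal and the curve equals the standard CI.
    """
    harr = _as_float_array(h, "h")
    if len(harr) != ranked.n:
        raise ValidationError("h and ranked sample have different lengths")
    if (harr < 0).any():
        raise ValidationError("h must be nonnegative")
    total = float(ranked.weight @ harr)
    if total == 0:
        raise UndefinedIndexError("mean of h is zero; curve undefined")
    n_cat = len(ranked.categories)
    w_c = np.bincount(ranked.category_code, weights=ranked.weight, minlength=n_cat)
    hw_c = np.bincount(
        ranked.category_code, weights=ranked.weight * harr, minlength=n_cat
    )
    observed = w_c > 0
    p = np.concatenate([[0.0], np.cumsum(w_c[observed])])
    L = np.concatenate([[0.0], np.cumsum(hw_c[observed]) / total])
    p[-1] = 1.0
    L[-1] = 1.0
    return CurveCoordinates(p=p, L=L)
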
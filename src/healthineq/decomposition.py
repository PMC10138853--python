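"""Regression-based decomposition of the Erreygers index.

For a binary outcome ``h`` with prevalence ``mu`` and ranking ``r``, the
standard concentration index admits the additive approximation::

    CI = sum_k (ME_k * xbar_k / mu) * CI_k  +  residual

where for each dummy regressor ``k`` in a survey-weighted binomial-logit
model, ``ME_k = beta_k * mean_w[p(1-p)]`` is the derivative-form average
marginal effect, ``xbar_k`` the weighted regressor mean, ``CI_k`` the
standard concentration index of the dummy against the same rank, and
``elasticity_k = ME_k * xbar_k / mu``.  A covariate's percent contribution is
``100 * elasticity_k * CI_k / CI``; positive contributions widen, negative
narrow, the measured inequality.  Contributions computed against the
standard CI are identical for the Erreygers-normalized decomposition, since
the 4*mu factor cancels from the ratio.

The derivative form of the marginal effect (not the discrete change) is used
throughout because the additive identity above requires elasticities that are
exactly linear in the coefficients.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .concentration import ConcentrationResult, RankedSample
from .exceptions import ConfigurationError, FitError, UndefinedIndexError, ValidationError

__all__ = [
    "GlmFit",
    "DecompositionTable",
    "build_design_matrix",
    "fit_outcome_model",
    "decompose",
    "interpret_signs",
]


@dataclass(frozen=True)
class GlmFit:
    """Survey-weighted binomial-logit fit with the quantities the
    decomposition needs: coefficients, fitted probabilities, derivative-form
    average marginal effects, and weighted regressor means."""

    params: pd.Series
    fitted: np.ndarray
    ame: pd.Series
    xbar: pd.Series
    prevalence: float
    converged: bool
    n: int
    blocks: Mapping[str, str]          # dummy name -> covariate it belongs to
    dropped: tuple = ()

    @property
    def elasticities(self) -> pd.Series:
        return self.ame * self.xbar / self.prevalence


@dataclass(frozen=True)
class DecompositionTable:
    """Per-dummy elasticity, concentration index and percent contribution,
    plus the explicit residual closing the additivity identity."""

    table: pd.DataFrame
    residual_pct: float
    outcome: str
    domain: str
    n: int
    prevalence: float
    eci: float

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Serialize in covariate / Elasticity / CI / % column order."""
        out = self.table[["covariate", "level", "elasticity",
                          "concentration_index", "contribution_pct"]].copy()
        out.columns = ["covariate", "level", "elasticity", "CI", "%"]
        resid = pd.DataFrame(
            [{"covariate": "residual", "level": "", "elasticity": np.nan,
              "CI": np.nan, "%": self.residual_pct}]
        )
        out = pd.concat([out, resid], ignore_index=True)
        for col in ("elasticity", "CI", "%"):
            out[col] = out[col].round(decimals)
        return out


def build_design_matrix(
    df: pd.DataFrame,
    covariates: Mapping[str, str],
) -> tuple[pd.DataFrame, dict]:
    """Dummy-code covariates against declared reference categories.

    ``covariates`` maps covariate column -> reference category.  Returns the
    design matrix (with intercept column ``const``) and a mapping from dummy
    name to its covariate block.
    """
    cols = {"const": np.ones(len(df))}
    blocks: dict[str, str] = {}
    for cov, ref in covariates.items():
        if cov not in df.columns:
            raise ConfigurationError(f"covariate column {cov!r} not in table")
        vals = df[cov]
        observed = list(pd.unique(vals.dropna()))
        if ref not in observed:
            raise ConfigurationError(
                f"reference category {ref!r} not observed for {cov!r}")
        if isinstance(vals.dtype, pd.CategoricalDtype):
            levels = [c for c in vals.cat.categories if c in observed]
        else:
            levels = sorted(observed, key=str)
        for cat in levels:
            if cat == ref:
                continue
            name = f"{cov}={cat}"
            cols[name] = (vals == cat).to_numpy(dtype=float)
            blocks[name] = cov
    X = pd.DataFrame(cols, index=df.index)
    return X, blocks


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns beyond the numerical rank via pivoted QR (never const)."""
    from scipy.linalg import qr

    arr = X.to_numpy(dtype=float)
    _, R, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(arr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)
    rank = int((diag > tol).sum())
    keep_idx = set(piv[:rank])
    keep_idx.add(0)  # const is column 0 by construction
    dropped = [X.columns[i] for i in range(arr.shape[1]) if i not in keep_idx]
    if dropped:
        warnings.warn(f"dropping collinear regressors: {dropped}", stacklevel=3)
        X = X.drop(columns=dropped)
    return X, dropped


def fit_outcome_model(
    df: pd.DataFrame,
    outcome: str,
    covariates: Mapping[str, str],
    weights: str | np.ndarray = "weight",
) -> GlmFit:
    """Weighted maximum-likelihood binomial-logit fit of a binary outcome.

    Point estimates are invariant to rescaling all weights. Non-convergent
    fits are retried from a ridge-stabilized start (helps sparse many-level
    covariates such as a 20-category ethnicity variable) before raising.
    """
    import statsmodels.api as sm

    y = pd.to_numeric(df[outcome], errors="coerce").to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError(f"outcome {outcome!r} has missing values; filter first")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError(f"outcome {outcome!r} is not binary")
    w = (pd.to_numeric(df[weights], errors="coerce").to_numpy(dtype=float)
         if isinstance(weights, str) else np.asarray(weights, dtype=float))
    if np.isnan(w).any() or (w <= 0).any():
        raise ValidationError("weights must be positive and non-missing")
    w = w / w.mean()  # normalization only affects the loglik scale

    X, blocks = build_design_matrix(df, covariates)
    X, dropped = _drop_collinear(X)
    blocks = {k: v for k, v in blocks.items() if k in X.columns}

    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200)
            converged = bool(res.converged)
        except Exception:
            res, converged = None, False
        if not converged:
            try:  # ridge-stabilized restart
                start = model.fit_regularized(alpha=1e-4, L1_wt=0.0).params
                res = model.fit(start_params=np.asarray(start), maxiter=200)
                converged = bool(res.converged)
            except Exception as exc:
                raise FitError(
                    f"{outcome}: logit fit failed even after ridge restart"
                ) from exc
    if res is None or not converged:
        raise FitError(f"{outcome}: logit fit did not converge")

    p = np.asarray(res.fittedvalues, dtype=float)
    wn = w / w.sum()
    m = float(wn @ (p * (1 - p)))
    params = pd.Series(res.params, index=X.columns)
    dummies = [c for c in X.columns if c != "const"]
    ame = params[dummies] * m
    xbar = pd.Series({k: float(wn @ X[k].to_numpy()) for k in dummies})
    return GlmFit(
        params=params,
        fitted=p,
        ame=ame,
        xbar=xbar,
        prevalence=float(wn @ y),
        converged=converged,
        n=len(y),
        blocks=blocks,
        dropped=tuple(dropped),
    )


def decompose(
    fit: GlmFit,
    ranked: RankedSample,
    result: ConcentrationResult,
    dummies: pd.DataFrame | None = None,
    outcome: str = "",
    domain: str = "",
) -> DecompositionTable:
    """Decompose an outcome's inequality into per-covariate contributions.

    ``ranked`` must be built on the same rows (and same rank variable) as the
    outcome's ``ConcentrationResult``; ``dummies`` is the dummy design matrix
    used in the fit (the ``build_design_matrix`` output).
    """
    if dummies is None:
        raise ValidationError("pass the dummy design matrix used in the fit")
    if len(dummies) != ranked.n:
        raise ValidationError("dummies and ranked sample differ in length")
    ci_std = result.ci_standard
    if ci_std == 0:
        raise UndefinedIndexError(
            "outcome concentration index is zero; percent contributions are "
            "undefined — report absolute contributions (elasticity * CI_k) instead"
        )
    w, r = ranked.weight, ranked.rank
    rbar = float(w @ r)
    rows = []
    for name in fit.ame.index:
        d = dummies[name].to_numpy(dtype=float)
        xbar = float(w @ d)
        cov = float(w @ ((d - xbar) * (r - rbar)))
        ci_k = 2.0 * cov / xbar if xbar > 0 else 0.0
        elas = float(fit.ame[name]) * xbar / result.prevalence
        rows.append({
            "covariate": fit.blocks.get(name, name),
            "level": name.split("=", 1)[1] if "=" in name else name,
            "elasticity": elas,
            "concentration_index": ci_k,
            "contribution_pct": 100.0 * elas * ci_k / ci_std,
        })
    table = pd.DataFrame(rows)
    residual = 100.0 - float(table["contribution_pct"].sum())
    return DecompositionTable(
        table=table,
        residual_pct=residual,
        outcome=outcome,
        domain=domain,
        n=fit.n,
        prevalence=result.prevalence,
        eci=result.eci,
    )


def interpret_signs(dt: DecompositionTable) -> pd.DataFrame:
    """Annotate each row with the direction of its effect.

    A positive percent contribution widens the measured inequality, a
    negative one narrows it; a positive elasticity means the covariate raises
    service use, a negative one lowers it.
    """
    out = dt.table.copy()
    out["inequality_effect"] = np.select(
        [out["contribution_pct"] > 0, out["contribution_pct"] < 0],
        ["widening", "narrowing"], default="neutral",
    )
    out["prevalence_effect"] = np.select(
        [out["elasticity"] > 0, out["elasticity"] < 0],
        ["increase", "decrease"], default="none",
    )
    return out
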
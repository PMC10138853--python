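"""Survey-weighted logit fits, marginal effects, and the decomposition identity."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from healthineq import (
    CategoricalSpec,
    GeneratorConfig,
    build_design_matrix,
    decompose,
    erreygers_result,
    fit_outcome_model,
    fractional_rank,
    generate_pooled_survey,
    interpret_signs,
    pool_and_rescale,
)
from healthineq.concentration import ConcentrationResult
from healthineq.decomposition import DecompositionTable
from healthineq.exceptions import ConfigurationError, UndefinedIndexError, ValidationError


def decompose_pair(df, outcome, domain, covariates, weight_col="weight"):
    sub = df[df[outcome].notna() & df[domain].notna()]
    covs = dict(covariates)
    covs.setdefault(domain, "low")
    rk = fractional_rank(sub[domain], sub[weight_col], order=["low", "medium", "high"])
    h = pd.to_numeric(sub[outcome]).to_numpy(float)
    res = erreygers_result(h, rk, cluster=sub["cluster"].to_numpy())
    fit = fit_outcome_model(sub, outcome, covs, weights=weight_col)
    X, _ = build_design_matrix(sub, covs)
    X = X[[c for c in X.columns if c in set(fit.ame.index) | {"const"}]]
    return decompose(fit, rk, res, dummies=X, outcome=outcome, domain=domain)


COVARIATES = {"residence": "rural", "wealth": "poorest", "education": "none",
              "media_exposure": "none", "occupation": "none"}


class TestFit:
    def test_exact_recovery_from_enumerated_cells(self):
        """Weighted fit on exact cell probabilities recovers log-odds 0 vs 2."""
        cells = pd.DataFrame({
            "x": ["a", "a", "b", "b"],
            "y": [0, 1, 0, 1],
        })
        from scipy.special import expit
        p_a, p_b = expit(0.0), expit(2.0)  # intercept 0, effect of b = 2
        cells["w"] = [0.5 * (1 - p_a), 0.5 * p_a, 0.5 * (1 - p_b), 0.5 * p_b]
        fit = fit_outcome_model(cells, "y", {"x": "a"}, weights="w")
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-6)
        assert fit.params["x=b"] == pytest.approx(2.0, abs=1e-6)

    def test_weight_rescaling_invariance(self, small_config):
        df, _ = generate_pooled_survey(small_config)
        f1 = fit_outcome_model(df, "early_anc", COVARIATES, weights="weight")
        df2 = df.assign(weight=df["weight"] * 2)
        f2 = fit_outcome_model(df2, "early_anc", COVARIATES, weights="weight")
        pd.testing.assert_series_equal(f1.params, f2.params, atol=1e-10, rtol=0)

    def test_null_model_elasticities_near_zero(self):
        coefs = {"early_anc": {"intercept": -0.4, "terms": {}}}
        cfg = GeneratorConfig(
            n_surveys=2, survey_years=(2011, 2016), strata_per_survey=10,
            clusters_per_stratum=10, women_per_cluster=25,
            outcome_coefficients=coefs, superpopulation_n=1000, seed=21,
        )
        df, _ = generate_pooled_survey(cfg)
        fit = fit_outcome_model(df, "early_anc", COVARIATES, weights="weight")
        assert fit.elasticities.abs().max() < 0.1

    def test_collinear_dummy_dropped_with_warning(self, small_config):
        df, _ = generate_pooled_survey(small_config)
        df["wealth_copy"] = df["wealth"]
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_outcome_model(
                df, "early_anc", {**COVARIATES, "wealth_copy": "poorest"},
                weights="weight")
        assert len(fit.dropped) == 4  # the duplicated wealth block

    def test_non_binary_outcome_rejected(self, small_config):
        df, _ = generate_pooled_survey(small_config)
        df["bad"] = 2
        with pytest.raises(ValidationError):
            fit_outcome_model(df, "bad", COVARIATES, weights="weight")


class TestDecompose:
    def test_additivity_identity(self, small_config):
        df, _ = generate_pooled_survey(small_config)
        dt = decompose_pair(df, "quality_anc", "attitude_to_violence", COVARIATES)
        assert dt.table["contribution_pct"].sum() + dt.residual_pct == pytest.approx(
            100.0, abs=1e-6)

    def test_rank_independent_covariate_contributes_nothing(self, four_unit_ranked):
        """ci_k = 0 forces a zero contribution regardless of elasticity."""
        import healthineq.decomposition as dc

        fit_ame = pd.Series({"z=b": 0.3})
        fit = dc.GlmFit(params=pd.Series({"const": 0.0, "z=b": 1.0}),
                        fitted=np.full(4, 0.5), ame=fit_ame,
                        xbar=pd.Series({"z=b": 0.5}), prevalence=0.5,
                        converged=True, n=4, blocks={"z=b": "z"})
        res = ConcentrationResult(prevalence=0.5, ci_standard=0.5, eci=1.0,
                                  se=0.0, ci95=(1.0, 1.0), n=4, method="linearized")
        # dummy uncorrelated with rank: balanced across rank halves
        X = pd.DataFrame({"const": np.ones(4), "z=b": [1.0, 0.0, 0.0, 1.0]})
        dt = dc.decompose(fit, four_unit_ranked, res, dummies=X)
        assert dt.table.loc[0, "contribution_pct"] == pytest.approx(0.0, abs=1e-12)

    def test_stratifier_driver_dominates_and_residual_small(self):
        """Outcome driven only by the stratifier (p = 0.35/0.5/0.65): its
        block carries nearly all the inequality; an independent covariate
        carries almost none."""
        emp = {"attitude_to_violence": CategoricalSpec(
            ("low", "medium", "high"), (1 / 3, 1 / 3, 1 / 3), 0.0)}
        cov = {"noise": CategoricalSpec(("a", "b"), (0.5, 0.5), 0.0)}
        logit = lambda p: float(np.log(p / (1 - p)))
        coefs = {"early_anc": {"intercept": logit(0.35), "terms": {
            ("attitude_to_violence", "medium"): logit(0.5) - logit(0.35),
            ("attitude_to_violence", "high"): logit(0.65) - logit(0.35),
        }}}
        cfg = GeneratorConfig(
            n_surveys=2, survey_years=(2011, 2016), strata_per_survey=10,
            clusters_per_stratum=10, women_per_cluster=50,
            covariate_spec=cov, empowerment_spec=emp, outcome_coefficients=coefs,
            year_effect=0.0, superpopulation_n=1000,
            omit_decision_first_survey=False, seed=31,
        )
        df, _ = generate_pooled_survey(cfg)
        dt = decompose_pair(df, "early_anc", "attitude_to_violence", {"noise": "a"})
        blocks = dt.table.groupby("covariate")["contribution_pct"].sum()
        assert blocks["attitude_to_violence"] > 80
        assert abs(blocks["noise"]) < 15
        assert abs(dt.residual_pct) < 15

    def test_single_driver_dominates_across_replicates(self):
        """With one rank-correlated covariate, its block contribution exceeds
        every other block's in (nearly) all replicates."""
        cov = {
            "wealth": CategoricalSpec(("q1", "q2", "q3"), (0.4, 0.35, 0.25), 0.7),
            "religion": CategoricalSpec(("r1", "r2"), (0.6, 0.4), 0.0),
            "occupation": CategoricalSpec(("o1", "o2"), (0.5, 0.5), 0.0),
        }
        coefs = {"early_anc": {"intercept": -1.0, "terms": {
            ("wealth", "q2"): 0.5, ("wealth", "q3"): 1.0}}}
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = GeneratorConfig(
                n_surveys=1, survey_years=(2016,), strata_per_survey=6,
                clusters_per_stratum=5, women_per_cluster=50,
                covariate_spec=cov, outcome_coefficients=coefs, year_effect=0.0,
                superpopulation_n=1000, omit_decision_first_survey=False,
                seed=40_000 + rep,
            )
            df, _ = generate_pooled_survey(cfg)
            dt = decompose_pair(
                df, "early_anc", "attitude_to_violence",
                {"wealth": "q1", "religion": "r1", "occupation": "o1"})
            blocks = dt.table.groupby("covariate")["contribution_pct"].sum().abs()
            others = blocks.drop(["wealth", "attitude_to_violence"])
            wins += int((blocks["wealth"] > others).all())
        assert wins >= 95

    def test_zero_outcome_ci_is_an_error(self, four_unit_ranked):
        import healthineq.decomposition as dc

        fit = dc.GlmFit(params=pd.Series({"const": 0.0}), fitted=np.full(4, 0.5),
                        ame=pd.Series(dtype=float), xbar=pd.Series(dtype=float),
                        prevalence=0.5, converged=True, n=4, blocks={})
        res = ConcentrationResult(prevalence=0.5, ci_standard=0.0, eci=0.0,
                                  se=0.0, ci95=(0.0, 0.0), n=4, method="linearized")
        X = pd.DataFrame({"const": np.ones(4)})
        with pytest.raises(UndefinedIndexError, match="absolute contributions"):
            dc.decompose(fit, four_unit_ranked, res, dummies=X)


class TestInterpretSigns:
    def test_annotations(self):
        table = pd.DataFrame({
            "covariate": ["wealth", "wealth", "x"],
            "level": ["poorer", "richest", "y"],
            "elasticity": [0.006, 0.051, 0.0],
            "concentration_index": [-0.08, 0.239, 0.0],
            "contribution_pct": [-0.281, 7.699, 0.0],
        })
        dt = DecompositionTable(table=table, residual_pct=0.0, outcome="o",
                                domain="d", n=3, prevalence=0.4, eci=0.1)
        out = interpret_signs(dt)
        assert out["inequality_effect"].tolist() == ["narrowing", "widening", "neutral"]
        assert out["prevalence_effect"].tolist() == ["increase", "increase", "none"]

    def test_serialized_table_order_and_residual_row(self):
        table = pd.DataFrame({
            "covariate": ["a"], "level": ["b"], "elasticity": [0.123456],
            "concentration_index": [0.2], "contribution_pct": [10.0],
        })
        dt = DecompositionTable(table=table, residual_pct=90.0, outcome="o",
                                domain="d", n=1, prevalence=0.4, eci=0.1)
        frame = dt.to_frame(decimals=3)
        assert list(frame.columns) == ["covariate", "level", "elasticity", "CI", "%"]
        assert frame.iloc[-1]["covariate"] == "residual"
        assert frame.iloc[0]["elasticity"] == 0.123
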
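"""DHS-like pooled survey generator with enumerated ground truth.

Emulates the structure of a pooled series of Demographic and Health Surveys:
several survey rounds, each a two-stage stratified cluster sample
(region x urban/rural strata, clusters as primary sampling units, a fixed
number of women per cluster), unequal sampling weights, ordinal three-level
empowerment domains, categorical socioeconomic covariates, and binary
maternal-health-service outcomes drawn from a logistic model with known
coefficients.

Dependence between the empowerment stratifier and the socioeconomic
covariates comes from a single latent "socioeconomic position" factor per
woman: each ordinal variable thresholds its own Gaussian draw, correlated
with the shared factor through a configurable loading (a Gaussian copula).
A cluster-level random intercept on the latent factor induces within-cluster
correlation; the outcome model itself depends only on the realized
covariates, so the population truth can be enumerated exactly from
conditional outcome probabilities.

Ground truth: the generator draws a large iid superpopulation from the same
covariate process (with the design's expected urban share and equal weights),
computes each woman's outcome probability, and enumerates the true Erreygers
index as ``8 * cov(p, r)`` — valid because ranks depend only on the
stratifier category while outcomes are conditionally independent Bernoulli
draws.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .exceptions import ConfigurationError, DegenerateRankingError

__all__ = [
    "CategoricalSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_pooled_survey",
    "inject_missingness",
    "write_pooled",
    "MISSING_SENTINEL",
    "default_covariate_spec",
    "default_empowerment_spec",
    "default_outcome_coefficients",
]

MISSING_SENTINEL = "dont_know"

EMPOWERMENT_DOMAINS = ("attitude_to_violence", "social_independence", "decision_making")
EMPOWERMENT_LEVELS = ("low", "medium", "high")

SWPER_ITEMS = (
    "beat_goes_out", "beat_neglects_children", "beat_argues",
    "beat_refuses_sex", "beat_burns_food",
    "freq_reading", "education_years", "age_first_cohabitation",
    "age_first_birth", "age_difference", "education_difference",
    "decide_health", "decide_purchases", "decide_visits",
)

# which domain each of the 14 items expresses
_ITEM_DOMAIN = dict(
    [(i, "attitude_to_violence") for i in SWPER_ITEMS[:5]]
    + [(i, "social_independence") for i in SWPER_ITEMS[5:11]]
    + [(i, "decision_making") for i in SWPER_ITEMS[11:]]
)


@dataclass(frozen=True)
class CategoricalSpec:
    """Marginal distribution of one ordinal/categorical variable and its
    copula loading on the shared socioeconomic latent factor."""

    categories: tuple
    probs: tuple
    latent_corr: float = 0.0

    def validate(self, name: str) -> None:
        if len(self.categories) != len(self.probs):
            raise ConfigurationError(f"{name}: categories and probs differ in length")
        p = np.asarray(self.probs, dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ConfigurationError(f"{name}: probabilities outside [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"{name}: probabilities must sum to 1")
        if not -1.0 < self.latent_corr < 1.0:
            raise ConfigurationError(f"{name}: latent_corr must be in (-1, 1)")


def default_covariate_spec() -> dict:
    """Covariates with category shares of DHS magnitude and moderate
    correlation with socioeconomic position."""
    return {
        "age_group": CategoricalSpec(("under20", "20plus"), (0.15, 0.85), 0.0),
        "wealth": CategoricalSpec(
            ("poorest", "poorer", "middle", "richer", "richest"),
            (0.18, 0.18, 0.19, 0.19, 0.26), 0.65,
        ),
        "education": CategoricalSpec(
            ("none", "primary", "secondary", "higher"),
            (0.60, 0.28, 0.09, 0.03), 0.60,
        ),
        "media_exposure": CategoricalSpec(
            ("none", "one", "two", "three"),
            (0.77, 0.16, 0.055, 0.015), 0.50,
        ),
        "occupation": CategoricalSpec(("none", "working"), (0.49, 0.51), 0.20),
        "religion": CategoricalSpec(
            ("orthodox", "protestant", "muslim_other"),
            (0.48, 0.20, 0.32), 0.0,
        ),
    }


def default_empowerment_spec() -> dict:
    """Three-level empowerment domains; category shares follow a pooled
    low-income-country survey profile."""
    return {
        "attitude_to_violence": CategoricalSpec(
            EMPOWERMENT_LEVELS, (0.59, 0.20, 0.21), 0.50),
        "social_independence": CategoricalSpec(
            EMPOWERMENT_LEVELS, (0.65, 0.26, 0.09), 0.60),
        "decision_making": CategoricalSpec(
            EMPOWERMENT_LEVELS, (0.12, 0.32, 0.56), 0.40),
    }


def default_outcome_coefficients() -> dict:
    """Log-odds of plausible magnitude for maternal-service outcomes.

    Each outcome model has an intercept plus per-dummy log-odds keyed
    ``(covariate, category)``; unlisted categories are references.
    """
    wealth_grad = {("wealth", "poorer"): 0.15, ("wealth", "middle"): 0.30,
                   ("wealth", "richer"): 0.50, ("wealth", "richest"): 0.90}
    edu_grad = {("education", "primary"): 0.30, ("education", "secondary"): 0.70,
                ("education", "higher"): 1.10}
    media_grad = {("media_exposure", "one"): 0.25, ("media_exposure", "two"): 0.45,
                  ("media_exposure", "three"): 0.60}
    attitude = {("attitude_to_violence", "medium"): 0.25,
                ("attitude_to_violence", "high"): 0.50}
    base = {**wealth_grad, **edu_grad, **media_grad, **attitude,
            ("residence", "urban"): 0.40}
    return {
        "early_anc": {"intercept": -1.9, "terms": dict(base)},
        "anc4plus": {"intercept": -1.4, "terms": dict(base)},
        "quality_anc": {"intercept": -1.1, "terms": dict(base)},
        "pnc2days": {"intercept": -2.1, "terms": dict(base)},
    }


@dataclass
class GeneratorConfig:
    """Configuration of the pooled-survey generator.

    Defaults emulate a four-round pooled DHS series: region x urban/rural
    strata, cluster primary sampling units, unequal lognormal weights, and
    outcome effects of the magnitude seen in maternal-health decomposition
    studies.
    """

    n_surveys: int = 4
    survey_years: tuple = (2000, 2005, 2011, 2016)
    strata_per_survey: int = 22
    clusters_per_stratum: int = 8
    women_per_cluster: int = 18
    weight_dispersion: float = 0.3
    cluster_latent_sd: float = 0.3
    urban_shift: float = 0.8
    covariate_spec: dict = field(default_factory=default_covariate_spec)
    empowerment_spec: dict = field(default_factory=default_empowerment_spec)
    outcome_coefficients: dict = field(default_factory=default_outcome_coefficients)
    year_effect: float = 0.25  # per-round log-odds drift in service use
    missing_rate: float = 0.0
    omit_decision_first_survey: bool = True
    generate_items: bool = False
    superpopulation_n: int = 1_000_000
    truth_outcome: str | None = None
    truth_domain: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_surveys", "strata_per_survey", "clusters_per_stratum",
                     "women_per_cluster"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if len(self.survey_years) < self.n_surveys:
            raise ConfigurationError("survey_years shorter than n_surveys")
        if self.weight_dispersion <= 0:
            raise ConfigurationError("weight_dispersion must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for name, spec in {**self.covariate_spec, **self.empowerment_spec}.items():
            spec.validate(name)
        for outcome, model in self.outcome_coefficients.items():
            if "intercept" not in model:
                raise ConfigurationError(f"{outcome}: outcome model needs an intercept")

    @property
    def urban_share(self) -> float:
        """Share of strata (hence of women, clusters being equal-sized) urban."""
        return sum(1 for s in range(self.strata_per_survey) if s % 2 == 0) / \
            self.strata_per_survey


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating coefficients plus the enumerated population truth for the
    designated (outcome, domain) pair; ``all_true_eci`` carries every pair."""

    coefficients: dict
    true_population_eci: float
    true_prevalence: float
    outcome: str
    domain: str
    superpopulation_n: int
    all_true_eci: dict
    all_true_prevalence: dict

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["coefficients"] = {
            o: {"intercept": m["intercept"],
                "terms": {f"{c}:{cat}": b for (c, cat), b in m["terms"].items()}}
            for o, m in self.coefficients.items()
        }
        return json.dumps(payload, indent=2)


def _thresholds(probs: np.ndarray) -> np.ndarray:
    """Gaussian quantile cutpoints turning N(0,1) draws into the marginal."""
    cum = np.cumsum(probs)[:-1]
    return ndtri(np.clip(cum, 1e-12, 1 - 1e-12))


def _draw_ordinal(spec: CategoricalSpec, z: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Categorical draw via thresholded Gaussian correlated with latent z."""
    rho = spec.latent_corr
    latent = rho * z + np.sqrt(1 - rho * rho) * rng.standard_normal(len(z))
    cuts = _thresholds(np.asarray(spec.probs, dtype=float))
    return np.searchsorted(cuts, latent, side="right")


def _standardized_latent(u: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Standardize the SES latent to zero mean / unit variance in the
    population implied by the design (urban-share mixture)."""
    q = config.urban_share
    mean = config.urban_shift * q
    var = 1.0 + config.cluster_latent_sd ** 2 + config.urban_shift ** 2 * q * (1 - q)
    return (u - mean) / np.sqrt(var)


def _covariate_frame(
    config: GeneratorConfig,
    urban: np.ndarray,
    cluster_effect: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw all covariates and empowerment domains given urban indicators and
    cluster random effects (zero in the superpopulation)."""
    n = len(urban)
    u = config.urban_shift * urban + cluster_effect + rng.standard_normal(n)
    z = _standardized_latent(u, config)
    out = {"residence": np.where(urban == 1, "urban", "rural")}
    for name, spec in config.covariate_spec.items():
        codes = _draw_ordinal(spec, z, rng)
        out[name] = np.asarray(spec.categories, dtype=object)[codes]
    for name, spec in config.empowerment_spec.items():
        codes = _draw_ordinal(spec, z, rng)
        out[name] = np.asarray(spec.categories, dtype=object)[codes]
        out[f"_{name}_latent"] = spec.latent_corr * z  # reused for item generation
    return pd.DataFrame(out)


def _linear_predictor(df: pd.DataFrame, model: dict, year_offset: np.ndarray) -> np.ndarray:
    eta = np.full(len(df), float(model["intercept"]))
    for (cov, cat), beta in model["terms"].items():
        if cov in df.columns:
            eta += beta * (df[cov].to_numpy() == cat)
    return eta + year_offset


def _generate_items(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Ordinal SWPER-style items expressing each woman's domain latent."""
    n = len(df)
    items = {}
    codings = {  # (levels, offset) per item family
        "beat": (2, 0), "freq_reading": (3, 0),
        "education_years": (16, 0), "age_first_cohabitation": (19, 12),
        "age_first_birth": (19, 12), "age_difference": (26, -10),
        "education_difference": (21, -10), "decide": (3, 1),
    }
    for item in SWPER_ITEMS:
        dom = _ITEM_DOMAIN[item]
        latent = df[f"_{dom}_latent"].to_numpy()
        noisy = 0.7 * latent + 0.714 * rng.standard_normal(n)
        fam = item.split("_")[0] if item.startswith(("beat", "decide")) else item
        levels, offset = codings[fam]
        cuts = ndtri(np.linspace(0, 1, levels + 1)[1:-1])
        items[item] = np.searchsorted(cuts, noisy, side="right") + offset
    return pd.DataFrame(items)


def _survey_table(
    config: GeneratorConfig, survey_idx: int, rng: np.random.Generator
) -> pd.DataFrame:
    year = config.survey_years[survey_idx]
    S, C, W = config.strata_per_survey, config.clusters_per_stratum, config.women_per_cluster
    n = S * C * W
    stratum_idx = np.repeat(np.arange(S), C * W)
    cluster_idx = np.repeat(np.arange(S * C), W)
    urban = (stratum_idx % 2 == 0).astype(float)

    cluster_effect = (config.cluster_latent_sd *
                      rng.standard_normal(S * C))[cluster_idx]
    df = _covariate_frame(config, urban, cluster_effect, rng)
    df["survey_year"] = year
    df["stratum"] = [f"s{year}_{i}" for i in stratum_idx]
    df["cluster"] = [f"c{year}_{i}" for i in cluster_idx]

    # design weights: lognormal cluster factors, normalized to mean 1 per survey
    wfac = np.exp(config.weight_dispersion * rng.standard_normal(S * C))
    weight = wfac[cluster_idx]
    df["weight"] = weight / weight.mean()

    year_offset = np.full(n, config.year_effect * survey_idx)
    for outcome, model in config.outcome_coefficients.items():
        p = expit(_linear_predictor(df, model, year_offset))
        df[outcome] = rng.binomial(1, p)

    if config.generate_items:
        df = pd.concat([df, _generate_items(df, rng)], axis=1)

    if config.omit_decision_first_survey and survey_idx == 0 and config.n_surveys > 1:
        # mirrors series where the decision-making domain is absent in round 1
        df["decision_making"] = pd.NA
        for item in SWPER_ITEMS[11:]:
            if item in df.columns:
                df[item] = pd.NA
    return df.drop(columns=[c for c in df.columns if c.startswith("_")])


def _enumerate_truth(config: GeneratorConfig, rng: np.random.Generator) -> SyntheticTruth:
    """Superpopulation enumeration of the true ECI and prevalence.

    Draws ``superpopulation_n`` iid women from the covariate process at the
    design's urban share (equal weights, no clustering: the cluster effect is
    part of the latent marginal), then uses conditional outcome probabilities:
    true ECI = 8 * cov(p_i, r_i) because E[h_i | covariates] = p_i and ranks
    depend only on the stratifier category.
    """
    n = config.superpopulation_n
    urban = rng.binomial(1, config.urban_share, size=n).astype(float)
    # iid draws absorb cluster heterogeneity into the latent's marginal sd
    cluster_effect = config.cluster_latent_sd * rng.standard_normal(n)
    df = _covariate_frame(config, urban, cluster_effect, rng)
    # pooled truth: average the survey-round drift over rounds
    offsets = config.year_effect * rng.integers(0, config.n_surveys, size=n)

    from .concentration import fractional_rank  # local import: avoid cycle

    w = np.ones(n)
    probs = {o: expit(_linear_predictor(df, m, offsets))
             for o, m in config.outcome_coefficients.items()}
    prev_all = {o: float(p.mean()) for o, p in probs.items()}
    eci_all: dict = {}
    for domain in config.empowerment_spec:
        order = list(config.empowerment_spec[domain].categories)
        try:
            rk = fractional_rank(df[domain], w, order=order)
        except DegenerateRankingError:
            # constant stratifier: the index (and its truth) is undefined
            eci_all[domain] = {o: float("nan") for o in probs}
            continue
        r = rk.rank
        rbar = r.mean()
        eci_all[domain] = {
            o: float(8.0 * np.mean((p - p.mean()) * (r - rbar)))
            for o, p in probs.items()
        }

    outcome = config.truth_outcome or next(iter(config.outcome_coefficients))
    domain = config.truth_domain or next(iter(config.empowerment_spec))
    return SyntheticTruth(
        coefficients=config.outcome_coefficients,
        true_population_eci=eci_all[domain][outcome],
        true_prevalence=prev_all[outcome],
        outcome=outcome,
        domain=domain,
        superpopulation_n=n,
        all_true_eci=eci_all,
        all_true_prevalence=prev_all,
    )


def generate_pooled_survey(config: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the pooled multi-survey table and its ground truth.

    One global seed stream is split deterministically per survey (and one for
    the truth enumeration), so regenerating any single survey reproduces it
    byte-identically.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_surveys + 2)
    tables = [
        _survey_table(config, s, np.random.default_rng(streams[s]))
        for s in range(config.n_surveys)
    ]
    df = pd.concat(tables, ignore_index=True)
    truth = _enumerate_truth(config, np.random.default_rng(streams[config.n_surveys]))
    if config.missing_rate > 0:
        miss_seed = int(streams[config.n_surveys + 1].generate_state(1)[0] % (2**31))
        df = inject_missingness(df, config.missing_rate, miss_seed,
                                columns=list(config.covariate_spec))
    return df, truth


def inject_missingness(
    table: pd.DataFrame,
    missing_rate: float,
    seed: int,
    columns: list[str] | None = None,
    sentinel: str = MISSING_SENTINEL,
) -> pd.DataFrame:
    """Replace a Bernoulli(``missing_rate``) fraction of eligible covariate
    cells with the "don't know" sentinel.

    Outcome and design variables (weight, stratum, cluster, survey year) are
    never made missing.
    """
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    protected = {"weight", "stratum", "cluster", "survey_year",
                 "early_anc", "anc4plus", "quality_anc", "pnc2days"}
    if columns is None:
        columns = [c for c in table.columns
                   if c not in protected and c not in EMPOWERMENT_DOMAINS]
    bad = protected.intersection(columns)
    if bad:
        raise ConfigurationError(f"cannot inject missingness into {sorted(bad)}")
    if missing_rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in columns:
        mask = rng.random(len(out)) < missing_rate
        if mask.any():
            vals = out[col].astype(object)
            vals[mask] = sentinel
            out[col] = vals
    return out


def write_pooled(df: pd.DataFrame, truth: SyntheticTruth, config: GeneratorConfig,
                 prefix: str) -> tuple[str, str]:
    """Write the table as CSV plus a JSON sidecar holding the truth and the
    exact generator configuration."""
    csv_path = f"{prefix}.csv"
    json_path = f"{prefix}.truth.json"
    df.to_csv(csv_path, index=False)
    cfg = dataclasses.asdict(config)
    for key in ("covariate_spec", "empowerment_spec"):
        cfg[key] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
                    for k, v in cfg[key].items()}
    cfg["outcome_coefficients"] = {
        o: {"intercept": m["intercept"],
            "terms": {f"{c}:{cat}": b for (c, cat), b in m["terms"].items()}}
        for o, m in cfg["outcome_coefficients"].items()
    }
    payload = json.loads(truth.to_json())
    payload["generator_config"] = cfg
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return csv_path, json_path
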
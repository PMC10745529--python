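"""Synthetic individual-level survey records.

The restricted survey microdata behind the analysis cannot be
redistributed, so this module generates records with the same statistical
structure: covariate marginals matching the published participant table
(n = 606 women aged 19-50), per-group food intakes whose means match the
baseline group-intake fixture, nutrient vectors derived from those intakes
through the groups' per-gram composition, and fasting triglycerides drawn
from a known log-linear model — which makes parameter recovery, stepwise
selection and scenario propagation testable against ground truth.

Generation model
----------------
* covariates: independent truncated normals / categoricals with the
  published means, SDs and proportions;
* group intake grams ~ Gamma(mean = fixture group mean, CV = ``intake_cv``)
  — right-skewed and non-negative, as daily food-group intakes are;
* per-person nutrients = sum over groups of grams x per-gram profile,
  jittered by a unit-mean lognormal per nutrient (``nutrient_noise_cv``)
  representing within-group food choice, so nutrient columns are not an
  exact linear function of the seven group intakes;
* log TG = beta_true . x + N(0, sigma).

Covariates are generated independently of one another and of intake,
mirroring the independence assumption of the downstream model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

from .composition import GroupIntakeTable, load_baseline_intakes
from .nutrients import ADDITIVE, NUTRIENTS, derived_gi
from .regression import build_design

__all__ = [
    "GeneratorConfig",
    "generate_population",
    "write_survey_csv",
    "read_survey_csv",
    "default_beta_true",
    "SURVEY_COLUMNS",
]

#: Documented column schema of the survey CSV.
SURVEY_COLUMNS: tuple[str, ...] = (
    "age", "bmi", "smoking_status", "country_of_birth",
    "family_history_diabetes", "hdl_c", "fasting_glucose",
    *NUTRIENTS,
    "triglycerides",
)

_CATEGORICAL = {
    "smoking_status": ("never", "ex", "current"),
    "country_of_birth": ("aus_nz", "other"),
}

# Published demographic marginals of the modelled sample.
_DEFAULT_MARGINALS: dict = {
    "age": {"mean": 36.38, "sd": 8.16, "lo": 19.0, "hi": 50.0},
    "bmi": {"mean": 26.56, "sd": 6.32, "lo": 14.0, "hi": np.inf},
    "hdl_c": {"mean": 1.47, "sd": 0.36, "lo": 0.0, "hi": np.inf},
    "fasting_glucose": {"mean": 4.85, "sd": 0.71, "lo": 0.0, "hi": np.inf},
    # category probabilities from the published counts (n = 606)
    "smoking_status": {"never": 362 / 606, "ex": 165 / 606, "current": 79 / 606},
    "country_of_birth": {"aus_nz": 443 / 606, "other": 163 / 606},
    "family_history_diabetes": {"p_yes": 179 / 606},
}

# Modest, plausible covariate effects on log TG used by the default truth.
_COVARIATE_BETA = {
    "age": 0.003,
    "bmi": 0.012,
    "hdl_c": -0.30,
    "fasting_glucose": 0.05,
    "smoking_status_ex": 0.01,
    "smoking_status_current": 0.04,
    "country_of_birth_other": 0.02,
    "family_history_diabetes": 0.03,
}


def default_beta_true() -> dict[str, float]:
    """Default true coefficient vector on the log-TG scale: the packaged
    demonstration nutrient coefficients plus modest covariate effects, with
    the intercept recentred so the population mean of the linear predictor
    stays at the demonstration baseline (median TG ~0.93 mmol/L)."""
    from .regression import load_demo_model

    demo = load_demo_model()
    beta = {k: float(v) for k, v in demo.params.items()}
    beta.update(_COVARIATE_BETA)
    m = _DEFAULT_MARGINALS
    cov_mean = (
        _COVARIATE_BETA["age"] * _trunc_mean(m["age"])
        + _COVARIATE_BETA["bmi"] * _trunc_mean(m["bmi"])
        + _COVARIATE_BETA["hdl_c"] * _trunc_mean(m["hdl_c"])
        + _COVARIATE_BETA["fasting_glucose"] * _trunc_mean(m["fasting_glucose"])
        + _COVARIATE_BETA["smoking_status_ex"] * m["smoking_status"]["ex"]
        + _COVARIATE_BETA["smoking_status_current"] * m["smoking_status"]["current"]
        + _COVARIATE_BETA["country_of_birth_other"] * m["country_of_birth"]["other"]
        + _COVARIATE_BETA["family_history_diabetes"]
        * m["family_history_diabetes"]["p_yes"]
    )
    beta["intercept"] = beta.get("intercept", 0.0) - cov_mean
    return beta


def _solve_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying normal (loc, scale) whose truncation to [lo, hi] has the
    requested mean and SD — the published moments describe the observed,
    i.e. already range-restricted, sample."""

    def moments(p):
        loc, scale = p
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return (
            stats.truncnorm.mean(a, b, loc=loc, scale=scale) - mean,
            stats.truncnorm.std(a, b, loc=loc, scale=scale) - sd,
        )

    from scipy.optimize import fsolve

    loc, scale = fsolve(moments, x0=[mean, sd], full_output=False)
    return float(loc), float(abs(scale))


_TRUNC_CACHE: dict[tuple, tuple[float, float]] = {}


def _trunc_params(spec: Mapping[str, float]) -> tuple[float, float, float, float]:
    key = (spec["mean"], spec["sd"], spec["lo"], spec["hi"])
    if key not in _TRUNC_CACHE:
        # unbounded-enough ranges need no moment matching
        a0 = (spec["lo"] - spec["mean"]) / spec["sd"]
        b0 = (spec["hi"] - spec["mean"]) / spec["sd"]
        if a0 < -4 and b0 > 4:
            _TRUNC_CACHE[key] = (spec["mean"], spec["sd"])
        else:
            _TRUNC_CACHE[key] = _solve_truncnorm(
                spec["mean"], spec["sd"], spec["lo"], spec["hi"]
            )
    loc, scale = _TRUNC_CACHE[key]
    return loc, scale, spec["lo"], spec["hi"]


def _trunc_mean(spec: Mapping[str, float]) -> float:
    return float(spec["mean"])


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic survey generator.

    ``beta_true`` maps design-column names (see
    :func:`dietsim.regression.build_design`) to true log-scale effects;
    ``sigma`` is the residual SD of log TG; ``intake_cv`` the coefficient
    of variation of the per-group Gamma intake distributions;
    ``nutrient_noise_cv`` the within-group composition jitter.
    ``correlation_hook`` is reserved for future correlated-covariate
    generation and must currently be ``None``.
    """

    n: int = 606
    seed: int = 0
    marginals: dict = dc_field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    beta_true: dict[str, float] = dc_field(default_factory=default_beta_true)
    sigma: float = 0.45
    intake_cv: float = 0.5
    nutrient_noise_cv: float = 0.10
    correlation_hook: object = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for key in ("smoking_status", "country_of_birth"):
            probs = [self.marginals[key][lvl] for lvl in _CATEGORICAL[key]]
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{key} probabilities must be >= 0 and sum to 1")
        for key in ("age", "bmi", "hdl_c", "fasting_glucose"):
            if self.marginals[key]["sd"] <= 0:
                raise ValueError(f"{key}: sd must be positive")
        if self.correlation_hook is not None:
            raise NotImplementedError("correlated covariate generation")


def _draw_truncnorm(rng, spec, n):
    loc, scale, lo, hi = _trunc_params(spec)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def generate_population(
    config: GeneratorConfig,
    baseline: GroupIntakeTable | None = None,
) -> pd.DataFrame:
    """Generate ``config.n`` individual records, deterministically for a
    given seed.  ``baseline`` supplies the group intake means and per-gram
    composition (defaults to the packaged baseline fixture)."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n, config.marginals
    if baseline is None:
        baseline = load_baseline_intakes()
    frame = baseline.to_frame()
    groups = list(frame.columns)

    df = pd.DataFrame(index=range(n))
    df["age"] = _draw_truncnorm(rng, m["age"], n)
    df["bmi"] = _draw_truncnorm(rng, m["bmi"], n)
    df["smoking_status"] = rng.choice(
        _CATEGORICAL["smoking_status"], size=n,
        p=[m["smoking_status"][lvl] for lvl in _CATEGORICAL["smoking_status"]],
    )
    df["country_of_birth"] = rng.choice(
        _CATEGORICAL["country_of_birth"], size=n,
        p=[m["country_of_birth"][lvl] for lvl in _CATEGORICAL["country_of_birth"]],
    )
    df["family_history_diabetes"] = (
        rng.random(n) < m["family_history_diabetes"]["p_yes"]
    ).astype(int)
    df["hdl_c"] = _draw_truncnorm(rng, m["hdl_c"], n)
    df["fasting_glucose"] = _draw_truncnorm(rng, m["fasting_glucose"], n)

    # per-group gram intakes ~ Gamma(mean = fixture mean, cv = intake_cv)
    cv = config.intake_cv
    shape = 1.0 / cv**2 if cv > 0 else None
    grams = {}
    for g in groups:
        mu = float(frame.loc["gram_weight", g])
        if cv > 0 and mu > 0:
            grams[g] = rng.gamma(shape, mu / shape, size=n)
        else:
            grams[g] = np.full(n, mu)
    # per-gram composition of each group (additive fields only)
    add = [f for f in NUTRIENTS if f in ADDITIVE and f != "gram_weight"]
    per_gram = frame.loc[add] / frame.loc["gram_weight"]
    nutr = np.zeros((n, len(add)))
    for g in groups:
        nutr += np.outer(grams[g], per_gram[g].to_numpy())
    # within-group food-choice jitter: unit-mean lognormal per nutrient
    ncv = config.nutrient_noise_cv
    if ncv > 0:
        s = float(np.sqrt(np.log1p(ncv**2)))
        nutr *= rng.lognormal(mean=-s**2 / 2.0, sigma=s, size=nutr.shape)
    df["gram_weight"] = sum(grams.values())
    for j, f in enumerate(add):
        df[f] = nutr[:, j]
    df["glycaemic_index"] = [
        derived_gi(gl, cho)
        for gl, cho in zip(df["glycaemic_load"], df["carbohydrate"])
    ]

    # outcome from the true log-linear model
    beta = config.beta_true
    X, _ = build_design(df, _terms_in(beta, df))
    eta = np.full(n, beta.get("intercept", 0.0))
    for c in X.columns:
        if c != "intercept" and c in beta:
            eta += beta[c] * X[c].to_numpy()
    noise = rng.normal(0.0, config.sigma, size=n) if config.sigma > 0 else 0.0
    df["triglycerides"] = np.exp(eta + noise)
    return df[list(SURVEY_COLUMNS)]


def _terms_in(beta: Mapping[str, float], df: pd.DataFrame) -> list[str]:
    """Model terms implied by the keys of a coefficient mapping."""
    terms = []
    for term, cols in (("smoking_status", ("smoking_status_ex", "smoking_status_current")),
                       ("country_of_birth", ("country_of_birth_other",))):
        if any(c in beta for c in cols):
            terms.append(term)
    for key in beta:
        if key == "intercept" or key in dict(
            smoking_status_ex=1, smoking_status_current=1, country_of_birth_other=1
        ):
            continue
        if key in df.columns:
            terms.append(key)
    return terms


# -- survey CSV round trip --------------------------------------------------

def write_survey_csv(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write records with the documented column schema."""
    missing = [c for c in SURVEY_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns {missing}")
    records[list(SURVEY_COLUMNS)].to_csv(path, index=False)


def read_survey_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read survey records; unknown columns are dropped with a warning,
    a missing triglycerides column is an error."""
    df = pd.read_csv(path, comment="#")
    unknown = [c for c in df.columns if c not in SURVEY_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown survey columns {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    if "triglycerides" not in df.columns:
        raise ValueError(f"{path}: survey file has no 'triglycerides' column")
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: survey file is missing columns {missing}")
    return df[list(SURVEY_COLUMNS)]
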
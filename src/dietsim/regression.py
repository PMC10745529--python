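"""Log-linear triglyceride regression and scenario prediction.

The biomarker model is ordinary least squares on log-transformed fasting
triglycerides::

    log TG_i = b0 + sum_j b_j x_ij + e_i,        e_i ~ N(0, s^2)

with covariates (age, BMI, country of birth, family history of diabetes,
smoking status, HDL-C, fasting glucose) and daily nutrient intakes as
predictors.  Model selection is backward stepwise by Akaike's Information
Criterion.  Population prediction applies the fitted coefficients to a
population-average covariate/nutrient vector; the point estimate is
``exp(x . b)`` and the 95% CI is the delta-method interval
``exp(x . b +- 1.96 sqrt(x' S x))`` with S the coefficient covariance.

The public surface is both functional (:func:`fit_ols_log_tg`,
:func:`backward_stepwise_aic`, :func:`predict_tg`) and a scikit-learn style
estimator (:class:`LogTriglycerideRegression`) usable with sklearn model
selection utilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .composition import GroupIntakeTable
from .nutrients import NUTRIENTS, NutrientVector, round_half_away

__all__ = [
    "TGModel",
    "ScenarioResult",
    "CollinearityError",
    "build_design",
    "fit_ols_log_tg",
    "backward_stepwise_aic",
    "predict_tg",
    "percent_change",
    "LogTriglycerideRegression",
    "load_demo_model",
    "evaluate_scenarios",
    "covariate_means",
    "COVARIATE_TERMS",
    "NUTRIENT_TERMS",
    "DEFAULT_TERMS",
]

#: Pre-determined (non-dietary) covariates.
COVARIATE_TERMS: tuple[str, ...] = (
    "age",
    "bmi",
    "country_of_birth",
    "family_history_diabetes",
    "smoking_status",
    "hdl_c",
    "fasting_glucose",
)

#: Dietary terms: energy, macronutrients, micronutrients, fatty acids,
#: alcohol and glycaemic index.  Gram weight and glycaemic load are
#: bookkeeping fields, not model terms.
NUTRIENT_TERMS: tuple[str, ...] = tuple(
    n for n in NUTRIENTS if n not in ("gram_weight", "glycaemic_load")
)

DEFAULT_TERMS: tuple[str, ...] = COVARIATE_TERMS + NUTRIENT_TERMS

#: Expansion of categorical terms into dummy design columns (reference
#: level first, omitted from the design).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "smoking_status": ("never", "ex", "current"),
    "country_of_birth": ("aus_nz", "other"),
}

class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


def _term_columns(term: str) -> list[str]:
    if term in CATEGORICAL_LEVELS:
        ref, *rest = CATEGORICAL_LEVELS[term]
        return [f"{term}_{lvl}" for lvl in rest]
    return [term]


def build_design(
    records: pd.DataFrame, terms: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric design matrix (with ``intercept`` column) and the mapping
    from model terms to their design columns (categoricals expand to
    dummy columns against the reference level)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(records))}
    groups: dict[str, list[str]] = {}
    for term in terms:
        if term not in records.columns:
            raise KeyError(f"term {term!r} not present in records")
        names = _term_columns(term)
        if term in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[term]
            vals = records[term].astype(str)
            bad = set(vals.unique()) - set(levels)
            if bad:
                raise ValueError(f"{term}: unknown categories {sorted(bad)}")
            for name, lvl in zip(names, levels[1:]):
                cols[name] = (vals == lvl).to_numpy(float)
        else:
            cols[term] = pd.to_numeric(records[term]).to_numpy(float)
        groups[term] = names
    X = pd.DataFrame(cols, index=records.index)
    return X, groups


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    # scale columns for a meaningful conditioning diagnostic
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    u, s, vt = np.linalg.svd(A / norms, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        involved = [
            X.columns[i] for i in np.nonzero(np.abs(vt[-1]) > 0.1)[0]
        ]
        raise CollinearityError(
            f"design matrix is rank deficient; collinear columns: {involved}"
        )
    cond = s[0] / s[-1]
    if cond > 1e6:
        warnings.warn(
            f"ill-conditioned design (condition number {cond:.3g}); "
            "energy and macronutrient terms are typically near-collinear — "
            "stepwise selection is left to resolve this",
            stacklevel=3,
        )


@dataclass
class TGModel:
    """A fitted (or externally supplied) log-triglyceride model.

    ``params``/``cov`` are indexed by design-column names, including
    ``intercept``.  ``aic`` follows the convention
    ``n * ln(RSS/n) + 2 * (k + 1)`` (k mean parameters, +1 for the residual
    variance); only AIC *differences* between candidate models are
    meaningful.  ``rmse`` is on the original mmol/L scale.
    """

    terms: tuple[str, ...]
    params: pd.Series
    cov: pd.DataFrame
    n: int = 0
    aic: float = float("nan")
    r2_log: float = float("nan")
    rmse: float = float("nan")
    transform: str = "log"
    smearing_factor: float = 1.0
    aic_trail: tuple[tuple[int, str, float], ...] = field(default=())

    @property
    def design_columns(self) -> list[str]:
        return [c for c in self.params.index if c != "intercept"]

    def linear_predictor(self, x: Mapping[str, float]) -> float:
        eta = float(self.params.get("intercept", 0.0))
        for c in self.design_columns:
            if c not in x:
                raise KeyError(f"prediction input is missing term {c!r}")
            eta += float(self.params[c]) * float(x[c])
        return eta

    def predict(
        self, x: Mapping[str, float], *, alpha: float = 0.05, smearing: bool = False
    ) -> tuple[float, tuple[float, float]]:
        """Population TG point estimate (mmol/L) and delta-method CI."""
        from scipy.stats import norm

        eta = self.linear_predictor(x)
        v = np.array([1.0, *(float(x[c]) for c in self.design_columns)])
        order = ["intercept", *self.design_columns]
        sigma = self.cov.reindex(index=order, columns=order).fillna(0.0).to_numpy()
        se = float(np.sqrt(max(v @ sigma @ v, 0.0)))
        z = norm.ppf(1 - alpha / 2)
        factor = self.smearing_factor if smearing else 1.0
        point = float(np.exp(eta)) * factor
        return point, (
            float(np.exp(eta - z * se)) * factor,
            float(np.exp(eta + z * se)) * factor,
        )

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_coefficients_csv(
        cls, path: Union[str, Path], cov_path: Union[str, Path, None] = None
    ) -> "TGModel":
        """Load a coefficient file: CSV of (term, beta, se).  Unless a
        covariance CSV is given, the covariance is diagonal in ``se**2``."""
        df = pd.read_csv(path, comment="#")
        need = {"term", "beta"}
        if not need <= set(df.columns):
            raise ValueError(f"{path}: coefficient file needs columns {need}")
        params = pd.Series(df["beta"].to_numpy(float), index=df["term"])
        if cov_path is not None:
            cov = pd.read_csv(cov_path, comment="#", index_col=0)
            cov = cov.reindex(index=params.index, columns=params.index)
        else:
            se = df["se"].to_numpy(float) if "se" in df else np.zeros(len(df))
            cov = pd.DataFrame(
                np.diag(se**2), index=params.index, columns=params.index
            )
        terms = tuple(t for t in params.index if t != "intercept")
        return cls(terms=terms, params=params, cov=cov)

    def report(self) -> dict:
        """JSON-friendly model summary."""
        return {
            "n": self.n,
            "terms": list(self.terms),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "aic": None if np.isnan(self.aic) else float(self.aic),
            "r2_log": None if np.isnan(self.r2_log) else float(self.r2_log),
            "rmse_mmol_l": None if np.isnan(self.rmse) else float(self.rmse),
            "aic_trail": [list(t) for t in self.aic_trail],
            "transform": self.transform,
        }


def _aic(rss: float, n: int, k: int) -> float:
    return n * float(np.log(rss / n)) + 2.0 * (k + 1)


def _fit(X: pd.DataFrame, logy: np.ndarray, y: np.ndarray,
         terms: tuple[str, ...]) -> TGModel:
    res = sm.OLS(logy, X).fit()
    rss = float(res.ssr)
    n, k = len(logy), X.shape[1]
    fitted = np.exp(res.fittedvalues)
    resid = logy - res.fittedvalues
    return TGModel(
        terms=terms,
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        n=n,
        aic=_aic(rss, n, k),
        r2_log=float(res.rsquared) if k > 1 else 0.0,
        rmse=float(np.sqrt(np.mean((fitted - y) ** 2))),
        smearing_factor=float(np.mean(np.exp(resid))),
    )


def fit_ols_log_tg(
    records: pd.DataFrame,
    terms: Sequence[str] = DEFAULT_TERMS,
    *,
    outcome: str = "triglycerides",
) -> TGModel:
    """Ordinary least squares of log triglycerides on the given terms.

    Raises :class:`CollinearityError` for a rank-deficient design and a
    plain ``ValueError`` when there are not enough observations
    (n must exceed the number of design columns + 1).
    """
    if outcome not in records.columns:
        raise KeyError(f"records have no outcome column {outcome!r}")
    y = pd.to_numeric(records[outcome]).to_numpy(float)
    if np.any(y <= 0):
        raise ValueError("triglycerides must be strictly positive for the log transform")
    X, _ = build_design(records, terms)
    if len(records) <= X.shape[1] + 1:
        raise ValueError(
            f"saturated design: n = {len(records)} observations for "
            f"{X.shape[1]} parameters"
        )
    _check_rank(X)
    return _fit(X, np.log(y), y, tuple(terms))


def backward_stepwise_aic(
    records: pd.DataFrame,
    terms: Sequence[str] = DEFAULT_TERMS,
    protected: Sequence[str] = (),
    *,
    outcome: str = "triglycerides",
) -> TGModel:
    """Backward stepwise selection by AIC.

    Starting from the full model, repeatedly deletes the single
    non-protected term whose removal yields the lowest AIC, as long as that
    AIC is strictly below the current model's.  Categorical terms are
    dropped as whole blocks.  Ties break lexicographically on term id.
    The audit trail of (step, dropped term, AIC after the drop) is attached
    to the returned model.
    """
    protected = set(protected)
    unknown = protected - set(terms)
    if unknown:
        raise ValueError(f"protected terms not in model: {sorted(unknown)}")
    y = pd.to_numeric(records[outcome]).to_numpy(float)
    if np.any(y <= 0):
        raise ValueError("triglycerides must be strictly positive for the log transform")
    logy = np.log(y)
    X_full, groups = build_design(records, terms)
    if len(records) <= X_full.shape[1] + 1:
        raise ValueError("saturated design in full model")
    _check_rank(X_full)

    def fit_subset(subset: tuple[str, ...]) -> TGModel:
        cols = ["intercept"]
        for t in subset:
            cols.extend(groups[t])
        return _fit(X_full[cols], logy, y, subset)

    current_terms = tuple(terms)
    current = fit_subset(current_terms)
    trail: list[tuple[int, str, float]] = []
    step = 0
    while True:
        candidates = sorted(t for t in current_terms if t not in protected)
        if not candidates:
            break
        best_term, best_model = None, None
        for t in candidates:
            reduced = tuple(x for x in current_terms if x != t)
            m = fit_subset(reduced)
            if best_model is None or m.aic < best_model.aic - 1e-12:
                best_term, best_model = t, m
        if best_model is not None and best_model.aic < current.aic - 1e-12:
            step += 1
            trail.append((step, best_term, best_model.aic))
            current_terms = best_model.terms
            current = best_model
        else:
            break
    current.aic_trail = tuple(trail)
    return current


def predict_tg(
    model: TGModel, x: Mapping[str, float], *, alpha: float = 0.05,
    smearing: bool = False,
) -> tuple[float, tuple[float, float]]:
    """Point prediction (mmol/L) and 95% CI for a population-average
    covariate + nutrient vector ``x`` (keys are design-column names)."""
    return model.predict(x, alpha=alpha, smearing=smearing)


def percent_change(
    baseline_point: float, modelled_point: float, *, ndigits: int | None = 1
) -> float:
    """Percent change of a modelled prediction against baseline,
    report-rounded (half away from zero) to ``ndigits`` decimals."""
    if baseline_point <= 0:
        raise ValueError("baseline prediction must be positive")
    pct = 100.0 * (modelled_point - baseline_point) / baseline_point
    return pct if ndigits is None else round_half_away(pct, ndigits)


def covariate_means(records: pd.DataFrame,
                    terms: Sequence[str] = COVARIATE_TERMS) -> dict[str, float]:
    """Design-column sample means of the non-dietary covariates; categorical
    dummies enter as proportions.  Used to hold covariates at their baseline
    values under every dietary scenario."""
    X, _ = build_design(records, [t for t in terms if t in records.columns])
    return {c: float(X[c].mean()) for c in X.columns if c != "intercept"}


# -- scikit-learn estimator -------------------------------------------------

class LogTriglycerideRegression(RegressorMixin, BaseEstimator):
    """Scikit-learn style wrapper around the log-TG model.

    Parameters
    ----------
    terms : sequence of str or None
        Model terms (columns of ``X``).  ``None`` uses every non-outcome
        column of the fitted frame that is a known term, in
        :data:`DEFAULT_TERMS` order.
    stepwise : bool
        Run backward stepwise AIC selection after the full fit.
    protected : sequence of str
        Terms stepwise may never drop.
    smearing : bool
        Apply Duan's smearing factor when back-transforming predictions.

    Attributes (after ``fit``)
    --------------------------
    model_ : TGModel
    params_ : pandas.Series of selected coefficients
    aic_, r2_, rmse_, n_ : fit statistics
    aic_trail_ : tuple of (step, dropped term, AIC)
    """

    def __init__(self, terms=None, stepwise=True, protected=(), smearing=False):
        self.terms = terms
        self.stepwise = stepwise
        self.protected = protected
        self.smearing = smearing

    def _resolve_terms(self, X: pd.DataFrame):
        if self.terms is not None:
            return tuple(self.terms)
        return tuple(t for t in DEFAULT_TERMS if t in X.columns)

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of named terms")
        records = X.copy()
        if y is None:
            if "triglycerides" not in records:
                raise ValueError("supply y or a 'triglycerides' column")
        else:
            records["triglycerides"] = np.asarray(y, float)
        terms = self._resolve_terms(records.drop(columns=["triglycerides"]))
        if self.stepwise:
            model = backward_stepwise_aic(records, terms, self.protected)
        else:
            model = fit_ols_log_tg(records, terms)
        self.model_ = model
        self.params_ = model.params
        self.aic_ = model.aic
        self.r2_ = model.r2_log
        self.rmse_ = model.rmse
        self.n_ = model.n
        self.aic_trail_ = model.aic_trail
        self.feature_names_in_ = np.asarray(terms, dtype=object)
        self.n_features_in_ = len(terms)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        D, _ = build_design(X, self.model_.terms)
        cols = ["intercept", *self.model_.design_columns]
        eta = D[cols].to_numpy() @ self.model_.params[cols].to_numpy()
        factor = self.model_.smearing_factor if self.smearing else 1.0
        return np.exp(eta) * factor

    def predict_population(self, x: Mapping[str, float], *, alpha: float = 0.05):
        """Point + CI for a population-average vector (delta method)."""
        return self.model_.predict(x, alpha=alpha, smearing=self.smearing)


# -- scenario evaluation ----------------------------------------------------

@dataclass(frozen=True)
class ScenarioResult:
    """Predicted population triglycerides for one scenario."""

    scenario_id: str
    baseline_tg: float
    baseline_ci: tuple[float, float]
    modelled_tg: float
    modelled_ci: tuple[float, float]
    absolute_change: float
    percent_change: float
    modelled_total: NutrientVector
    tags: tuple[str, ...] = ()

    def to_row(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "baseline_tg": self.baseline_tg,
            "baseline_ci_lower": self.baseline_ci[0],
            "baseline_ci_upper": self.baseline_ci[1],
            "modelled_tg": self.modelled_tg,
            "modelled_ci_lower": self.modelled_ci[0],
            "modelled_ci_upper": self.modelled_ci[1],
            "absolute_change": self.absolute_change,
            "percent_change": self.percent_change,
            "tags": ";".join(self.tags),
        }


def _x_from_total(total: NutrientVector, covariates: Mapping[str, float]) -> dict:
    x = dict(covariates)
    x.update(total.to_dict())
    return x


def evaluate_scenarios(
    model: TGModel,
    baseline: GroupIntakeTable,
    specs,
    *,
    covariates: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    smearing: bool = False,
) -> list[ScenarioResult]:
    """Run each scenario and propagate the nutrient totals through the TG
    model.  Non-dietary covariate entries (if the model selected any) are
    held fixed at the supplied baseline means for every scenario."""
    from .scenarios import run_scenario

    covariates = dict(covariates or {})
    base_total = baseline.aggregate_total()
    b_point, b_ci = model.predict(
        _x_from_total(base_total, covariates), alpha=alpha, smearing=smearing
    )
    results = []
    for spec in specs:
        modelled = run_scenario(baseline, spec)
        total = modelled.aggregate_total()
        m_point, m_ci = model.predict(
            _x_from_total(total, covariates), alpha=alpha, smearing=smearing
        )
        results.append(ScenarioResult(
            scenario_id=spec.id,
            baseline_tg=b_point,
            baseline_ci=b_ci,
            modelled_tg=m_point,
            modelled_ci=m_ci,
            absolute_change=m_point - b_point,
            percent_change=percent_change(b_point, m_point, ndigits=None),
            modelled_total=total,
            tags=spec.tags,
        ))
    return results


def load_demo_model() -> TGModel:
    """The packaged demonstration coefficient file (nutrient-only log-TG
    model calibrated to the published baseline prediction; see the file
    header — these are not the survey-fitted coefficients)."""
    import importlib.resources

    path = importlib.resources.files("dietsim.data").joinpath("demo_coefficients.csv")
    with importlib.resources.as_file(path) as p:
        return TGModel.from_coefficients_csv(p)
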
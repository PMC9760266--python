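"""Clinical variable screening and linear diagnostic-index models.

The screen tests each covariate against the binary early-deterioration
outcome: continuous laboratory values with the pooled-variance (Student)
two-sample t-test, categorical covariates (sex, primary site, stage,
ECOG performance status, age dichotomized at 65 years, BMI at 22 kg/m²)
with Pearson's chi-square without continuity correction.  Variables with
p < 0.05 are carried into a multivariate linear-probability model: ordinary
least squares of the 0/1 outcome on the selected covariates, with
performance status entered as an integer score.  The fitted intercept and
coefficients form a scalar "diagnostic index" whose value predicts early
deterioration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "pooled_t_from_summary",
    "chi_square_test",
    "univariate_screen",
    "screen_from_summary",
    "LinearIndex",
    "DiagnosticIndexModel",
    "DiagnosticIndexResults",
    "fit_linear_index",
    "evaluate_index",
]

#: laboratory covariates tested as continuous in the univariate screen
SCREEN_CONTINUOUS = ("Alb", "AST", "ALT", "ChE", "LDH", "T-Bil", "BUN", "Cre",
                     "Na", "K", "Cl", "RBC", "Hb", "Plt", "CRP", "Neut", "Lymp")
#: covariates tested as categorical (age and BMI after dichotomization)
SCREEN_CATEGORICAL = ("age_ge_65", "sex", "primary_site", "stage", "ps", "bmi_ge_22")


def pooled_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from group summary statistics.

    Returns (t, two-sided p) with df = n1 + n2 - 2.  Group 1 minus group 2
    in the numerator.
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("group SDs must be positive")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on an r x c table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def _screen_row(variable, test, statistic, df, p, alpha, summary):
    return {"variable": variable, "test": test, "statistic": statistic, "df": df,
            "p_value": p, "selected": bool(p < alpha), "summary": summary}


def univariate_screen(cohort: pd.DataFrame, alpha: float = 0.05,
                      outcome: str = "early_deterioration") -> pd.DataFrame:
    """Screen every covariate against the outcome; selected iff p < alpha.

    Constant variables yield p = 1 with a warning instead of failing.
    """
    y = cohort[outcome].astype(int)
    if y.nunique() != 2 or y.value_counts().min() < 2:
        raise ValueError("screen requires at least 2 patients in each outcome group")
    g0, g1 = cohort[y == 0], cohort[y == 1]

    work = cohort.copy()
    if "age" in work:
        work["age_ge_65"] = np.where(work["age"] >= 65, ">=65", "<65")
    if "bmi" in work:
        work["bmi_ge_22"] = np.where(work["bmi"] >= 22, ">=22", "<22")

    rows = []
    for var in SCREEN_CONTINUOUS:
        if var not in cohort:
            continue
        x0, x1 = g0[var].to_numpy(float), g1[var].to_numpy(float)
        if np.std(np.concatenate([x0, x1])) == 0:
            warnings.warn(f"{var} is constant; screen p set to 1")
            rows.append(_screen_row(var, "pooled_t", 0.0, len(y) - 2, 1.0, alpha, {}))
            continue
        t, p = pooled_t_from_summary(x0.mean(), x0.std(ddof=1), len(x0),
                                     x1.mean(), x1.std(ddof=1), len(x1))
        summ = {"mean0": x0.mean(), "sd0": x0.std(ddof=1), "mean1": x1.mean(), "sd1": x1.std(ddof=1)}
        rows.append(_screen_row(var, "pooled_t", t, len(y) - 2, p, alpha, summ))

    for var in SCREEN_CATEGORICAL:
        if var not in work:
            continue
        tab = pd.crosstab(work[var], y)
        if tab.shape[0] < 2:
            warnings.warn(f"{var} is constant; screen p set to 1")
            rows.append(_screen_row(var, "chi_square", 0.0, 0, 1.0, alpha, {}))
            continue
        chi2, df, p = chi_square_test(tab.to_numpy())
        rows.append(_screen_row(var, "chi_square", chi2, df, p, alpha,
                                {"counts": tab.to_dict()}))
    return pd.DataFrame(rows).set_index("variable")


def screen_from_summary(continuous: Mapping[str, tuple], categorical: Mapping[str, Sequence[Sequence[float]]],
                        n0: int, n1: int, alpha: float = 0.05) -> pd.DataFrame:
    """Screen from printed group summaries rather than patient-level data.

    ``continuous`` maps variable -> (mean0, sd0, mean1, sd1); ``categorical``
    maps variable -> contingency table (categories x groups).
    """
    rows = []
    for var, (m0, s0, m1, s1) in continuous.items():
        t, p = pooled_t_from_summary(m0, s0, n0, m1, s1, n1)
        rows.append(_screen_row(var, "pooled_t", t, n0 + n1 - 2, p, alpha,
                                {"mean0": m0, "sd0": s0, "mean1": m1, "sd1": s1}))
    for var, tab in categorical.items():
        chi2, df, p = chi_square_test(tab)
        rows.append(_screen_row(var, "chi_square", chi2, df, p, alpha, {}))
    return pd.DataFrame(rows).set_index("variable")


# --- linear diagnostic index ----------------------------------------------

@dataclass(frozen=True)
class LinearIndex:
    """Scalar diagnostic index: intercept + sum of coefficient x covariate."""

    intercept: float
    coefficients: Mapping[str, float]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def evaluate(self, covariates) -> float | pd.Series:
        """Evaluate on a mapping (scalar) or DataFrame (per-row Series)."""
        if isinstance(covariates, pd.DataFrame):
            missing = [v for v in self.coefficients if v not in covariates.columns]
            if missing:
                raise KeyError(f"missing covariates: {missing}")
            out = pd.Series(self.intercept, index=covariates.index, dtype=float)
            for var, coef in self.coefficients.items():
                out = out + coef * covariates[var].astype(float)
            return out
        missing = [v for v in self.coefficients if v not in covariates]
        if missing:
            raise KeyError(f"missing covariates: {missing}")
        return float(self.intercept + sum(c * float(covariates[v]) for v, c in self.coefficients.items()))

    __call__ = evaluate

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"intercept = {self.intercept!r}\n")
            for var, coef in self.coefficients.items():
                fh.write(f"{var} = {coef!r}\n")

    @classmethod
    def from_text(cls, path) -> "LinearIndex":
        intercept, coefs = 0.0, {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, val = (s.strip() for s in line.split("=", 1))
                if key == "intercept":
                    intercept = float(val)
                else:
                    coefs[key] = float(val)
        return cls(intercept=intercept, coefficients=coefs)


class DiagnosticIndexModel:
    """Linear-probability model of the 0/1 outcome on named covariates.

    statsmodels-style: construct from a DataFrame, ``fit()`` returns a
    :class:`DiagnosticIndexResults`.  ``family="logistic"`` switches to a
    logit fit of the same design for sensitivity analyses.
    """

    def __init__(self, data: pd.DataFrame, variables: Sequence[str],
                 outcome: str = "early_deterioration", family: str = "linear"):
        if family not in ("linear", "logistic"):
            raise ValueError("family must be 'linear' or 'logistic'")
        missing = [v for v in variables if v not in data.columns]
        if missing:
            raise KeyError(f"missing covariates: {missing}")
        if data[list(variables)].isna().any().any():
            raise ValueError("missing values in design; complete data required")
        self.variables = list(variables)
        self.outcome = outcome
        self.family = family
        self.data = data
        self.endog = data[outcome].astype(float).to_numpy()
        X = data[self.variables].astype(float)
        if len(X) <= len(self.variables) + 1:
            raise ValueError("need n > number of variables + 1")
        self.exog = sm.add_constant(X, has_constant="add")
        self._check_rank()

    def _check_rank(self) -> None:
        arr = self.exog.to_numpy()
        rank = np.linalg.matrix_rank(arr)
        if rank < arr.shape[1]:
            _, r = np.linalg.qr(arr)
            diag = np.abs(np.diag(r))
            bad = [self.exog.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    @classmethod
    def from_screen(cls, cohort: pd.DataFrame, screen: pd.DataFrame, **kwargs) -> "DiagnosticIndexModel":
        """Build the multivariate model from a screen table.

        Selected continuous variables enter as-is; a selected performance
        status enters as its integer score; other selected categoricals
        (site, stage, dichotomized age/BMI, sex) are not carried into the
        index model.
        """
        selected = list(screen.index[screen["selected"]])
        variables = [v for v in selected if v in SCREEN_CONTINUOUS]
        if "ps" in selected:
            variables.append("ps")
        data = cohort.copy()
        if "ps" in variables:
            data["ps"] = data["ps"].astype(int)
        return cls(data, variables, **kwargs)

    def fit(self) -> "DiagnosticIndexResults":
        if self.family == "linear":
            res = sm.OLS(self.endog, self.exog).fit()
        else:
            res = sm.Logit(self.endog, self.exog).fit(disp=0)
        return DiagnosticIndexResults(self, res)


class DiagnosticIndexResults:
    """Fitted diagnostic-index model: coefficients, uncertainties, summary."""

    def __init__(self, model: DiagnosticIndexModel, sm_results):
        self.model = model
        self._res = sm_results
        self.params = sm_results.params
        self.bse = sm_results.bse
        self.pvalues = sm_results.pvalues
        self.fittedvalues = pd.Series(np.asarray(sm_results.fittedvalues),
                                      index=model.data.index)

    @property
    def index_model(self) -> LinearIndex:
        coefs = {v: float(self.params[v]) for v in self.model.variables}
        return LinearIndex(intercept=float(self.params["const"]), coefficients=coefs)

    def predict(self, data: pd.DataFrame) -> pd.Series:
        return self.index_model.evaluate(data)

    def summary(self):
        return self._res.summary()

    def __repr__(self) -> str:
        terms = ", ".join(f"{v}={self.params[v]:.4g}" for v in self.model.variables)
        return f"<DiagnosticIndexResults intercept={self.params['const']:.4g}, {terms}>"


def fit_linear_index(cohort: pd.DataFrame, variables: Sequence[str],
                     outcome: str = "early_deterioration") -> DiagnosticIndexResults:
    """OLS of the binary outcome on ``variables`` (PS as integer score)."""
    data = cohort.copy()
    if "ps" in variables:
        data["ps"] = data["ps"].astype(int)
    return DiagnosticIndexModel(data, variables, outcome=outcome).fit()


def evaluate_index(model: LinearIndex, covariates) -> float | pd.Series:
    """Evaluate a linear index on covariates (order-independent)."""
    return model.evaluate(covariates)
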
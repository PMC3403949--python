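"""Predictive body-mass regression and estimation from limb circumferences.

Body mass of quadrupeds scales tightly with the minimum diaphyseal
circumferences of the humerus and femur.  This module fits ordinary
least squares predictive models on log10-transformed data, scores them
(R^2, SEE, AIC, and mean percent prediction error with a 95% CI),
detects residual and extreme outliers, registers the published
predictive equations, and converts circumferences of extinct taxa into
point estimates with PPE-based plausibility ranges.

PPE (percent prediction error) for one species is
|observed - predicted| / predicted * 100 on the back-transformed (raw
mass) scale; the predicted value is the denominator.  SEE is
sqrt(RSS/(n - k - 1)) on the log scale.  AIC is the Gaussian
profile-likelihood form n*ln(RSS/n) + 2(k + 2), comparable only within
one dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
import statsmodels.api as sm

__all__ = [
    "RegressionModel",
    "MassEstimate",
    "OutlierReport",
    "fit_ols",
    "prediction_error",
    "ppe_values",
    "fit_power_nls",
    "detect_residual_outliers",
    "detect_extreme_outliers",
    "published_equations",
    "estimate_mass",
    "compare_mean_ttest",
]


@dataclass
class RegressionModel:
    """A log10-linear predictive model of body mass (grams)."""

    model_id: str
    predictor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    n: int | None = None
    R2: float | None = None
    SEE: float | None = None
    AIC: float | None = None
    mean_ppe: float | None = None  # percent
    ppe_ci: tuple[float, float] | None = None  # percent
    method: str = "OLS"
    log_base: float = 10.0
    se: np.ndarray | None = None  # intercept first, then coefficients

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.predictor_names):
            raise ValueError("coefficient count must equal predictor count")

    def predict_log(self, X) -> np.ndarray:
        """Predicted log10 body mass for rows of log10 predictors."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients

    def slope_ci(self, which: int = 0, alpha: float = 0.05) -> tuple[float, float]:
        """t-based CI for one coefficient (df = n - k - 1)."""
        if self.se is None or self.n is None:
            raise ValueError("model carries no standard errors")
        df = self.n - len(self.coefficients) - 1
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        m, s = float(self.coefficients[which]), float(self.se[1 + which])
        return (m - tcrit * s, m + tcrit * s)


def _design(samples: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    names = list(samples)
    X = np.column_stack([np.asarray(samples[nm], dtype=float) for nm in names])
    return names, X


def fit_ols(
    samples: dict[str, np.ndarray],
    response: np.ndarray,
    model_id: str = "ols_fit",
) -> RegressionModel:
    """Least-squares regression of log mass on one or more log predictors.

    Scores the fitted model in-sample: R^2, SEE, AIC, and the mean PPE
    with its 95% CI on the back-transformed scale.
    """
    names, X = _design(samples)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > predictors + 1")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    if res.df_model < k:
        raise ValueError("rank-deficient design matrix")
    rss = float(res.ssr)
    see = math.sqrt(rss / (n - k - 1))
    aic = n * math.log(rss / n) + 2 * (k + 2) if rss > 0 else -math.inf
    model = RegressionModel(
        model_id=model_id,
        predictor_names=names,
        coefficients=res.params[1:],
        intercept=float(res.params[0]),
        n=n,
        R2=float(res.rsquared),
        SEE=see,
        AIC=aic,
        se=np.asarray(res.bse),
    )
    model.mean_ppe, model.ppe_ci = prediction_error(model, samples, y)
    return model


def ppe_values(model: RegressionModel, samples, response) -> np.ndarray:
    """Per-species percent prediction errors on the raw mass scale."""
    _, X = _design(samples)
    pred = model.log_base ** model.predict_log(X)
    obs = model.log_base ** np.asarray(response, dtype=float)
    return np.abs(obs - pred) / pred * 100.0


def prediction_error(
    model: RegressionModel, samples, response, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Mean PPE with a t-based (1 - alpha) confidence interval."""
    ppe = ppe_values(model, samples, response)
    n = len(ppe)
    mean = float(np.mean(ppe))
    if n < 2:
        return mean, (mean, mean)
    half = stats.t.ppf(1 - alpha / 2, n - 1) * np.std(ppe, ddof=1) / math.sqrt(n)
    return mean, (mean - float(half), mean + float(half))


def fit_power_nls(
    raw_x: np.ndarray, raw_y: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Fit y = a * x^b on untransformed data by Levenberg-Marquardt.

    Initialized from the log-log OLS fit; returns (a, b, residuals).
    """
    x = np.asarray(raw_x, dtype=float)
    y = np.asarray(raw_y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power fit requires positive raw values")
    init = fit_ols({"x": np.log10(x)}, np.log10(y), "nls_init")
    p0 = (10.0 ** init.intercept, float(init.coefficients[0]))
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.power(t, b), x, y, p0=p0,
            method="lm", maxfev=200 * (len(x) + 1),
        )
    except RuntimeError as exc:
        raise RuntimeError(f"power-law NLS did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    return a, b, y - a * np.power(x, b)


@dataclass
class OutlierReport:
    method: str
    statistics: dict[str, float]
    flagged: list[str]
    thresholds: dict[str, float] = field(default_factory=dict)


def detect_residual_outliers(
    samples: dict[str, np.ndarray],
    response: np.ndarray,
    species: list[str] | None = None,
    alpha: float = 0.05,
) -> OutlierReport:
    """Flag residual outliers by externally studentized residuals.

    A species is flagged when its |studentized residual| exceeds the
    two-tailed t critical value at the Bonferroni-corrected family level
    alpha/n (df = n - k - 2).
    """
    _, X = _design(samples)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("need n > predictors + 2")
    species = species or [f"obs{i}" for i in range(n)]
    res = sm.OLS(y, sm.add_constant(X)).fit()
    if res.ssr <= np.finfo(float).eps * max(1.0, float(y @ y)):
        # numerically exact fit: no residual structure to flag
        return OutlierReport(
            method="studentized_bonferroni",
            statistics={sp: 0.0 for sp in species},
            flagged=[],
            thresholds={"alpha": alpha},
        )
    student = np.asarray(res.outlier_test(method="bonf"))[:, 0]
    crit = stats.t.ppf(1 - alpha / (2 * n), n - k - 2)
    flagged = [sp for sp, t in zip(species, student) if abs(t) > crit]
    return OutlierReport(
        method="studentized_bonferroni",
        statistics=dict(zip(species, map(float, student))),
        flagged=flagged,
        thresholds={"critical_t": float(crit), "alpha": alpha},
    )


def detect_extreme_outliers(
    values: np.ndarray, labels: list[str] | None = None
) -> OutlierReport:
    """Tukey fences: flag values outside quartiles -/+ 1.5 * IQR.

    Quartiles are linearly interpolated (numpy default, R type 7).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values")
    labels = labels or [f"obs{i}" for i in range(len(v))]
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = [lab for lab, val in zip(labels, v) if val < lo or val > hi]
    return OutlierReport(
        method="tukey_fences",
        statistics=dict(zip(labels, map(float, v))),
        flagged=flagged,
        thresholds={"lower": float(lo), "upper": float(hi)},
    )


def published_equations() -> dict[str, RegressionModel]:
    """The six published body-mass predictors (grams from millimetres).

    eq1/eq2 are the universal combined-circumference equations (OLS and
    PGLS); eq3/eq4 use all four limb measurements; eq5/eq6 use the two
    circumferences.  Mean PPE is recorded where published (25.6% for eq1,
    25% for eq2); the remaining models carry no PPE and yield
    point-estimate-only output.
    """
    return {
        "eq1": RegressionModel(
            "eq1", ["C_H+F"], [2.749], -1.104,
            n=245, R2=0.988, mean_ppe=25.6, method="OLS",
        ),
        "eq2": RegressionModel(
            "eq2", ["C_H+F"], [2.754], -1.097,
            mean_ppe=25.0, method="PGLS",
        ),
        "eq3": RegressionModel(
            "eq3", ["L_H", "C_H", "L_F", "C_F"],
            [0.375, 1.544, -0.136, 0.954], -0.351, method="OLS",
        ),
        "eq4": RegressionModel(
            "eq4", ["L_H", "C_H", "L_F", "C_F"],
            [0.212, 1.347, -0.533, 0.749], -0.76, method="PGLS",
        ),
        "eq5": RegressionModel(
            "eq5", ["C_H", "C_F"], [1.78, 0.939], -0.215, method="OLS",
        ),
        "eq6": RegressionModel(
            "eq6", ["C_H", "C_F"], [1.54, 1.195], -0.234, method="PGLS",
        ),
    }


@dataclass
class MassEstimate:
    """Back-transformed point estimate (grams) with PPE range."""

    point_g: float
    lower_g: float
    upper_g: float
    model_id: str
    inputs_mm: dict[str, float]

    @property
    def point_kg(self) -> float:
        return self.point_g / 1000.0

    @property
    def lower_kg(self) -> float:
        return self.lower_g / 1000.0

    @property
    def upper_kg(self) -> float:
        return self.upper_g / 1000.0


def estimate_mass(
    c_humerus: float | None,
    c_femur: float | None,
    model: RegressionModel,
    lengths: dict[str, float] | None = None,
) -> MassEstimate:
    """Estimate body mass from stylopodial circumferences (millimetres).

    The plausibility range is point * (1 -/+ mean_ppe/100).  Length-based
    predictors, when the model requires them, are supplied through
    ``lengths``.
    """
    available: dict[str, float] = dict(lengths or {})
    if c_humerus is not None:
        available["C_H"] = c_humerus
    if c_femur is not None:
        available["C_F"] = c_femur
    if c_humerus is not None and c_femur is not None:
        available["C_H+F"] = c_humerus + c_femur
    row = []
    for nm in model.predictor_names:
        if nm not in available:
            raise ValueError(f"model {model.model_id} needs predictor {nm}")
        if available[nm] <= 0:
            raise ValueError(f"non-positive input for {nm}")
        row.append(math.log10(available[nm]))
    point = float(model.log_base ** model.predict_log(np.array([row]))[0])
    if model.mean_ppe is None:
        warnings.warn(
            f"model {model.model_id} has no published mean PPE; "
            "returning a point estimate without a range",
            stacklevel=2,
        )
        lo = hi = point
    else:
        lo = point * (1 - model.mean_ppe / 100.0)
        hi = point * (1 + model.mean_ppe / 100.0)
    used = {nm: available[nm] for nm in model.predictor_names}
    return MassEstimate(point, lo, hi, model.model_id, used)


def compare_mean_ttest(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample two-tailed t-test; statistic sign follows a - b."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite df
    na, nb = len(a), len(b)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return float(t), float(df), float(p)
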
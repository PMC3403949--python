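"""Standardized major axis (SMA) line fitting and comparison.

SMA (reduced major axis) regression is the symmetric line-fitting method
used for interspecific scaling: the slope magnitude is sd_y/sd_x and the
line passes through the bivariate mean.  This module provides the slope
confidence interval, slope hypothesis tests against theoretical scaling
exponents, a likelihood-ratio test for common slopes among groups, an
elevation (intercept) t-test evaluated at arbitrary abscissae, and
Benjamini-Hochberg FDR correction for families of pairwise comparisons.

Theoretical similarity models give the exponents tested: geometric (GS),
elastic (ES) and static (SS) similarity predict circumference ~ length^1,
^1.5, ^2; mass ~ length^3, ^4, ^5; and mass ~ circumference^3, ^8/3, ^5/2
respectively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .core_data import BivariateLogSample

__all__ = [
    "SMAFit",
    "SlopeTest",
    "SimilarityVerdict",
    "ComparisonCell",
    "MODEL_EXPONENTS",
    "fit_sma",
    "slope_ci_from_summary",
    "test_slope_value",
    "classify_similarity",
    "compare_slopes_lrt",
    "compare_intercepts",
    "adjust_fdr",
    "pairwise_comparison_matrix",
]


@dataclass
class SMAFit:
    """SMA line fit of a log-log bivariate sample."""

    n: int
    m: float
    b: float
    r: float
    R2: float
    ci_lower: float
    ci_upper: float
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    min_x: float
    alpha: float = 0.05

    @property
    def resid_var(self) -> float:
        """Sample variance of y - m*x (SMA residual scores)."""
        cov = self.r * math.sqrt(self.var_x * self.var_y)
        return self.var_y - 2 * self.m * cov + self.m**2 * self.var_x

    @property
    def slope_var(self) -> float:
        """Large-sample variance of the SMA slope, m^2 (1-r^2)/(n-2)."""
        return self.m**2 * (1 - self.r**2) / (self.n - 2)

    def elevation(self, x_star: float = 0.0) -> float:
        """Height of the fitted line at ``x_star`` (the intercept at 0)."""
        return self.m * x_star + self.b


def slope_ci_from_summary(
    m: float, n: int, r2: float, alpha: float = 0.05, df: int | None = None
) -> tuple[float, float]:
    """Slope CI from summary statistics alone.

    Uses B = F(1-alpha; 1, df) * (1-r^2)/df with df = n-2 and returns
    m*(sqrt(B+1) -/+ sqrt(B)).  Separated out so intervals can be
    recomputed from published (m, n, R^2) triples.
    """
    if df is None:
        df = n - 2
    B = stats.f.ppf(1 - alpha, 1, df) * (1 - r2) / df
    lo = m * (math.sqrt(B + 1) - math.sqrt(B))
    hi = m * (math.sqrt(B + 1) + math.sqrt(B))
    return (lo, hi) if m >= 0 else (hi, lo)


def fit_sma(sample: BivariateLogSample, alpha: float = 0.05) -> SMAFit:
    """Fit the standardized major axis to a bivariate log sample.

    slope = sign(r) * sd_y/sd_x, line through the means.  Raises on zero
    variance in either axis and on exactly zero correlation (the SMA slope
    sign is then undefined).
    """
    x, y, n = sample.x, sample.y, sample.n
    var_x = float(np.var(x, ddof=1))
    var_y = float(np.var(y, ddof=1))
    if var_x <= 0 or var_y <= 0:
        raise ValueError("SMA requires positive variance on both axes")
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        raise ValueError("correlation is exactly zero: SMA slope sign undefined")
    m = math.copysign(math.sqrt(var_y / var_x), r)
    mean_x, mean_y = float(np.mean(x)), float(np.mean(y))
    b = mean_y - m * mean_x
    lo, hi = slope_ci_from_summary(m, n, r * r, alpha)
    return SMAFit(
        n=n, m=m, b=b, r=r, R2=r * r, ci_lower=lo, ci_upper=hi,
        mean_x=mean_x, mean_y=mean_y, var_x=var_x, var_y=var_y,
        min_x=float(np.min(x)), alpha=alpha,
    )


@dataclass
class SlopeTest:
    statistic: float
    df: int
    p: float


def test_slope_value(
    fit: SMAFit, sample: BivariateLogSample, b0: float
) -> SlopeTest:
    """Test H0: SMA slope == b0 (Warton residual-vs-axis correlation test).

    The correlation r_rf between residual scores y - b0*x and axis scores
    y + b0*x is zero exactly when b0 is the SMA slope; the test statistic
    is t = r_rf * sqrt((n-2)/(1-r_rf^2)) on n-2 df, two-tailed.
    """
    if b0 == 0:
        raise ValueError("b0 must be nonzero")
    x, y, n = sample.x, sample.y, sample.n
    u = y - b0 * x
    v = y + b0 * x
    su, sv = np.std(u, ddof=1), np.std(v, ddof=1)
    scale = math.sqrt(np.var(y, ddof=1) + b0 * b0 * np.var(x, ddof=1))
    degenerate = su <= 1e-12 * scale or sv <= 1e-12 * scale
    if not degenerate:
        r_rf = float(np.corrcoef(u, v)[0, 1])
        degenerate = abs(r_rf) >= 1.0 - 1e-14
    if degenerate:
        # (numerically) collinear sample: the slope is known exactly
        if math.isclose(b0, fit.m, rel_tol=1e-9, abs_tol=1e-12):
            return SlopeTest(0.0, n - 2, 1.0)
        raise ValueError("degenerate (collinear) sample with b0 != fitted slope")
    t = r_rf * math.sqrt((n - 2) / (1 - r_rf**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return SlopeTest(t, n - 2, p)


#: model exponents per relation kind, in G/E/S (geometric/elastic/static) order
MODEL_EXPONENTS: dict[str, dict[str, float]] = {
    "circumference~length": {"G": 1.0, "E": 1.5, "S": 2.0},
    "mass~length": {"G": 3.0, "E": 4.0, "S": 5.0},
    "mass~circumference": {"G": 3.0, "E": 8.0 / 3.0, "S": 2.5},
}

_MODEL_ORDER = ("G", "E", "S")


@dataclass
class SimilarityVerdict:
    """Which theoretical scaling models a fitted slope is consistent with."""

    relation_kind: str
    consistent_models: set[str]
    code: str


def classify_similarity(
    fit: SMAFit,
    sample: BivariateLogSample,
    relation_kind: str | None,
    alpha: float = 0.05,
) -> SimilarityVerdict:
    """Classify a fitted slope against the registered similarity models.

    Each model exponent is tested with :func:`test_slope_value`; models not
    rejected at ``alpha`` are listed.  With none consistent, a slope lying
    strictly between two adjacent model exponents is coded relative to both
    (e.g. "> G, < E"); a slope outside the span of all exponents is "0".
    Relations with no registered models (e.g. femur length vs humerus
    length) return "-".
    """
    if relation_kind is None or relation_kind not in MODEL_EXPONENTS:
        return SimilarityVerdict(relation_kind or "", set(), "-")
    exps = MODEL_EXPONENTS[relation_kind]
    consistent = set()
    for name, e in exps.items():
        try:
            if test_slope_value(fit, sample, e).p >= alpha:
                consistent.add(name)
        except ValueError:
            # collinear sample whose exact slope differs from e: reject
            continue
    if consistent:
        code = ", ".join(nm for nm in _MODEL_ORDER if nm in consistent)
        return SimilarityVerdict(relation_kind, consistent, code)
    by_value = sorted(exps.items(), key=lambda kv: kv[1])
    values = [v for _, v in by_value]
    if values[0] < fit.m < values[-1]:
        for (nm_lo, e_lo), (nm_hi, e_hi) in zip(by_value, by_value[1:]):
            if e_lo < fit.m < e_hi:
                pair = {nm_lo: ">", nm_hi: "<"}
                code = ", ".join(
                    f"{pair[nm]} {nm}" for nm in _MODEL_ORDER if nm in pair
                )
                return SimilarityVerdict(relation_kind, set(), code)
    return SimilarityVerdict(relation_kind, set(), "0")


def _group_moments(samples: list[BivariateLogSample]):
    n = np.array([s.n for s in samples], dtype=float)
    vx = np.array([np.var(s.x, ddof=1) for s in samples])
    vy = np.array([np.var(s.y, ddof=1) for s in samples])
    cxy = np.array(
        [np.cov(s.x, s.y, ddof=1)[0, 1] for s in samples]
    )
    return n, vx, vy, cxy


def compare_slopes_lrt(
    samples: list[BivariateLogSample],
) -> tuple[float, float, int, float]:
    """Likelihood-ratio test for a common SMA slope across groups.

    The profile log-likelihood of slope b in group i is
    (n_i/2) * ln(1 - r_uv,i(b)^2), where r_uv is the correlation between
    the rotated residual (y - b x) and axis (y + b x) scores; it is
    maximal (zero) at the group's own SMA slope.  The common slope
    maximizes the sum and the statistic -2*(logL_common - sum logL_separate)
    = -sum n_i ln(1 - r_uv,i(b_hat)^2) is referred to chi^2 with g-1 df.

    Returns ``(common_slope, statistic, df, p)``.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    n, vx, vy, cxy = _group_moments(samples)
    slopes = np.sign(cxy) * np.sqrt(vy / vx)
    if not (np.all(slopes > 0) or np.all(slopes < 0)):
        raise ValueError("groups have SMA slopes of mixed sign")

    def neg2_loglik(b: float) -> float:
        cov_uv = vy - b * b * vx
        var_u = vy - 2 * b * cxy + b * b * vx
        var_v = vy + 2 * b * cxy + b * b * vx
        r2 = cov_uv**2 / (var_u * var_v)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        return float(-np.sum(n * np.log1p(-r2)))

    lo = min(0.5 * slopes.min(), 2.0 * slopes.min())
    hi = max(0.5 * slopes.max(), 2.0 * slopes.max())
    res = optimize.minimize_scalar(
        neg2_loglik, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10 * max(abs(lo), abs(hi))},
    )
    if not res.success:
        raise RuntimeError(
            f"common-slope optimization failed on bracket [{lo}, {hi}]: {res.message}"
        )
    stat = res.fun
    df = len(samples) - 1
    p = float(stats.chi2.sf(stat, df))
    return float(res.x), float(stat), df, p


def compare_intercepts(
    fit_a: SMAFit, fit_b: SMAFit, x_star: float = 0.0
) -> tuple[float, int, float]:
    """t-test comparing SMA line elevations at abscissa ``x_star``.

    With x_star = 0 this compares the classical intercepts; evaluating at
    the minimum x of the pooled data avoids extrapolating the lines to a
    biologically meaningless size of 1 mm.  The standard error combines
    each group's residual variance and slope variance by the delta method:
    SE^2 = sum_i [ s2_resid,i / n_i + (mean_x,i - x*)^2 * Var(m_i) ].
    df = n_1 + n_2 - 4, two-tailed p.
    """
    if not math.isfinite(x_star):
        raise ValueError("x_star must be finite")
    diff = fit_a.elevation(x_star) - fit_b.elevation(x_star)
    se2 = sum(
        f.resid_var / f.n + (f.mean_x - x_star) ** 2 * f.slope_var
        for f in (fit_a, fit_b)
    )
    df = fit_a.n + fit_b.n - 4
    scale = max(abs(fit_a.elevation(x_star)), abs(fit_b.elevation(x_star)), 1.0)
    if se2 <= (1e-12 * scale) ** 2:
        if abs(diff) <= 1e-9 * scale:
            return 0.0, df, 1.0
        raise ValueError("zero elevation SE with unequal elevations")
    t = diff / math.sqrt(se2)
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonCell:
    """One pairwise group comparison within an analysis family."""

    group_a: str
    group_b: str
    analysis: str
    ci_overlap: bool
    common_slope: float
    lrt_stat: float
    lrt_p: float
    t_intercept: float
    p_intercept: float
    t_shifted: float
    p_shifted: float
    x_star: float
    lrt_p_fdr: float = math.nan
    p_intercept_fdr: float = math.nan
    p_shifted_fdr: float = math.nan


def pairwise_comparison_matrix(
    groups: dict[str, BivariateLogSample],
    analysis: str = "",
    x_star: float | str = "pooled_min",
    alpha: float = 0.05,
    min_n: int = 10,
) -> list[ComparisonCell]:
    """All pairwise SMA comparisons among labeled groups, FDR-corrected.

    For every unordered group pair: slope-CI overlap, the common-slope LRT,
    and elevation t-tests at x = 0 and at the shifted abscissa (by default
    the minimum x over all included groups).  The three p-value families
    are each Benjamini-Hochberg adjusted across the cells of this call —
    the comparisons of one analysis form one FDR family.  Groups below
    ``min_n`` are dropped with a warning.
    """
    kept: dict[str, BivariateLogSample] = {}
    for label, s in groups.items():
        if s.n < min_n:
            warnings.warn(
                f"group {label!r} excluded from comparisons (n={s.n} < {min_n})",
                stacklevel=2,
            )
        else:
            kept[label] = s
    if len(kept) < 2:
        return []
    fits = {lab: fit_sma(s, alpha) for lab, s in kept.items()}
    if x_star == "pooled_min":
        x_star = min(f.min_x for f in fits.values())
    labels = list(kept)
    cells: list[ComparisonCell] = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            fa, fb = fits[a], fits[b]
            overlap = fa.ci_lower <= fb.ci_upper and fb.ci_lower <= fa.ci_upper
            common, lrt_stat, _, lrt_p = compare_slopes_lrt([kept[a], kept[b]])
            t0, _, p0 = compare_intercepts(fa, fb, 0.0)
            ts, _, ps = compare_intercepts(fa, fb, x_star)
            cells.append(ComparisonCell(
                group_a=a, group_b=b, analysis=analysis, ci_overlap=overlap,
                common_slope=common, lrt_stat=lrt_stat, lrt_p=lrt_p,
                t_intercept=t0, p_intercept=p0,
                t_shifted=ts, p_shifted=ps, x_star=float(x_star),
            ))
    for raw, adj in [
        ("lrt_p", "lrt_p_fdr"),
        ("p_intercept", "p_intercept_fdr"),
        ("p_shifted", "p_shifted_fdr"),
    ]:
        adjusted = adjust_fdr([getattr(c, raw) for c in cells])
        for c, v in zip(cells, adjusted):
            setattr(c, adj, float(v))
    return cells
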
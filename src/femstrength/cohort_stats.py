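"""Small-sample cohort statistics for strength-predictor analysis.

The workflow mirrors the statistical treatment of a two-arm observational
study with ~10 subjects per arm: exact Mann-Whitney U tests for group
differences, Spearman rank correlations against femoral strength, and a
ladder of nested ordinary-least-squares models whose goodness of fit is
compared by adjusted R-squared.  Because the samples are tiny, exact
p-values are used wherever feasible (rank-assignment enumeration for the
U test, full permutation for Spearman) and the method actually used is
always recorded alongside the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

#: Largest combined sample for which the U test enumerates exactly.
EXACT_U_LIMIT = 20

#: Largest n for which the Spearman p is a full permutation enumeration.
EXACT_SPEARMAN_LIMIT = 9


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    extra: dict = field(default_factory=dict)


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution (enumeration over rank assignments)
    when the combined sample is at most 20 and tie-free; otherwise mid-ranks
    with the tie-corrected normal approximation (no continuity correction,
    the convention of mainstream statistics packages for reported exact/
    asymptotic U tests).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= EXACT_U_LIMIT and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        method = "normal-approximation-tie-corrected"
    return TestResult(float(res.statistic), float(res.pvalue), method)


def _spearman_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with an exact permutation p for small n.

    rho is the Pearson correlation of mid-ranks.  For n <= 9 the two-sided
    p-value enumerates all n! permutations of one rank vector; larger
    samples use the t approximation.  Constant input has undefined rho,
    reported as NaN with p = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = _spearman_rho(xr, yr)
    if np.isnan(rho):
        return TestResult(np.nan, np.nan, "undefined-constant-input")
    n = x.size
    if n <= EXACT_SPEARMAN_LIMIT:
        perms = np.array(list(itertools.permutations(range(n))), dtype=float)
        yp = yr[perms.astype(int)]
        xc = xr - xr.mean()
        ypc = yp - yp.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc ** 2).sum() * (ypc ** 2).sum(axis=1))
        rhos = (ypc @ xc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return TestResult(rho, p, "exact-permutation")
    t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return TestResult(rho, min(p, 1.0), "t-approximation")


def quartile_summary(values) -> tuple[float, float, float]:
    """Median (Q1, Q3) with linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Regression ladder
# ---------------------------------------------------------------------------

@dataclass
class RegressionModel:
    """One fitted rung of the model ladder (or a published model).

    ``coefficients`` maps predictor name -> unstandardized B (the intercept
    under ``"const"``); ``std_coefficients`` are the betas from z-scored
    variables; CIs are 95% two-sided from the t distribution.
    """

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    std_coefficients: dict[str, float] = field(default_factory=dict)
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    adjusted_r_squared: float = np.nan
    r_squared: float = np.nan
    n: int = 0
    fittable: bool = True
    note: str = ""

    def improved_over(self, previous: "RegressionModel | None") -> bool:
        if previous is None or not self.fittable or not previous.fittable:
            return False
        return self.adjusted_r_squared > previous.adjusted_r_squared


def fit_ols(table: pd.DataFrame, response: str,
            predictors: tuple[str, ...]) -> RegressionModel:
    """OLS with adjusted R², standardized betas and 95% CIs for one rung."""
    n = len(table)
    p = len(predictors)
    if n <= p + 1:
        return RegressionModel(response, tuple(predictors), {}, n=n,
                               fittable=False,
                               note="adjusted R-squared undefined (n <= p + 1)")
    y = table[response].to_numpy(dtype=float)
    X = table[list(predictors)].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        return RegressionModel(response, tuple(predictors), {}, n=n,
                               fittable=False,
                               note="rank-deficient design (no outputs)")
    fit = sm.OLS(y, Xc).fit()
    names = ["const", *predictors]
    coefs = dict(zip(names, fit.params))
    ci = fit.conf_int(alpha=0.05)
    conf = {nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)}
    pvals = dict(zip(names, (float(v) for v in fit.pvalues)))
    # Standardized betas: slope scaled by SD(x)/SD(y).
    sy = y.std(ddof=1)
    betas = {nm: float(coefs[nm] * X[:, k].std(ddof=1) / sy)
             for k, nm in enumerate(predictors)} if sy > 0 else {}
    return RegressionModel(
        response=response, predictors=tuple(predictors),
        coefficients={k: float(v) for k, v in coefs.items()},
        std_coefficients=betas, conf_int=conf, p_values=pvals,
        adjusted_r_squared=float(fit.rsquared_adj),
        r_squared=float(fit.rsquared), n=n,
    )


def collinearity_screen(table: pd.DataFrame, response: str,
                        candidates: list[str],
                        threshold: float = 0.8) -> list[str]:
    """Drop the weaker of any candidate pair with |r| above the threshold.

    When two candidates are strongly inter-correlated, the one less
    (Pearson-)correlated with the response is removed — e.g. femoral BMD
    yields to the femoral neck T score when both track strength.
    """
    kept = list(candidates)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(kept, 2):
            r = abs(table[a].corr(table[b]))
            if r > threshold:
                ra = abs(table[a].corr(table[response]))
                rb = abs(table[b].corr(table[response]))
                kept.remove(a if ra < rb else b)
                changed = True
                break
    return kept


def fit_ladder(table: pd.DataFrame, base: str, additions: list[str],
               response: str = "femoral_strength") -> list[RegressionModel]:
    """Fit the nested model ladder base, base+a1, base+a1+a2, ...

    Each rung is an OLS fit; rungs whose adjusted R-squared improves on the
    previous fittable rung are flagged via ``improved`` in ``extra``.
    Row order of the table does not affect the fits.
    """
    models: list[RegressionModel] = []
    predictors: list[str] = [base]
    prev: RegressionModel | None = None
    for extra in [None, *additions]:
        if extra is not None:
            predictors.append(extra)
        m = fit_ols(table, response, tuple(predictors))
        m.note = (m.note + " improved").strip() if m.improved_over(prev) else m.note
        models.append(m)
        if m.fittable:
            prev = m
    return models


def predict_strength(model: RegressionModel, covariates: dict[str, float]) -> float:
    """Linear predictor B0 + sum(Bi * xi) for the model's covariates (N)."""
    if not model.fittable:
        raise ValueError("model was not fittable")
    missing = [p for p in model.predictors if p not in covariates]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    return float(model.coefficients.get("const", 0.0)
                 + sum(model.coefficients[p] * covariates[p]
                       for p in model.predictors))


# ---------------------------------------------------------------------------
# Published best models (clinical reference coefficients)
# ---------------------------------------------------------------------------

def published_best_model(group: str) -> RegressionModel:
    """Published best femoral-strength model for a study arm.

    ``group`` is ``"t2dm"`` (predictors: femoral neck T score, pentosidine,
    age, HbA1c, P1NP) or ``"control"`` (T score, BMI, P1NP).  Coefficients
    are the reported unstandardized B values, usable with
    :func:`predict_strength` on covariates in the study's units.
    """
    if group == "t2dm":
        return RegressionModel(
            response="femoral_strength",
            predictors=("fn_t_score", "pentosidine", "age", "hba1c", "p1np"),
            coefficients={"const": 29240.848, "fn_t_score": 315.404,
                          "pentosidine": -14.118, "age": -153.863,
                          "hba1c": -879.085, "p1np": 161.406},
            std_coefficients={"fn_t_score": 0.235, "pentosidine": -0.754,
                              "age": -0.572, "hba1c": -0.484, "p1np": 0.347},
            adjusted_r_squared=0.961, n=10,
        )
    if group == "control":
        return RegressionModel(
            response="femoral_strength",
            predictors=("fn_t_score", "bmi", "p1np"),
            coefficients={"const": 9584.833, "fn_t_score": 745.051,
                          "bmi": -40.206, "p1np": -13.840},
            std_coefficients={"fn_t_score": 1.083, "bmi": -0.200,
                              "p1np": -0.508},
            adjusted_r_squared=0.930, n=8,
        )
    raise ValueError(f"unknown group {group!r}; expected 't2dm' or 'control'")


#: The published ladder of predictor additions on top of the T-score base.
PUBLISHED_LADDER = ["pentosidine", "age", "hba1c", "p1np", "bmi", "c_peptide"]


def group_comparison(table: pd.DataFrame, columns: list[str],
                     group_col: str = "group") -> pd.DataFrame:
    """Quartile summaries and U-test p for each column across the two groups."""
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for col in columns:
        a = table.loc[table[group_col] == groups[0], col]
        b = table.loc[table[group_col] == groups[1], col]
        res = mann_whitney(a, b)
        ma, q1a, q3a = quartile_summary(a)
        mb, q1b, q3b = quartile_summary(b)
        rows.append({
            "parameter": col,
            f"{groups[0]}_median_q1_q3": f"{ma:.4g} ({q1a:.4g}, {q3a:.4g})",
            f"{groups[1]}_median_q1_q3": f"{mb:.4g} ({q1b:.4g}, {q3b:.4g})",
            "U": res.statistic, "p_value": res.p_value, "method": res.method,
        })
    return pd.DataFrame(rows)
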
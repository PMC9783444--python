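"""Cohort-level statistical battery for subject FD tables.

Implements the analysis battery applied to the 10 regional fractal dimension
measures of a cross-sectional cohort: per-measure extreme-outlier removal
(3 x IQR fences), multiple linear regression of each FD on age, sex, and
total brain volume (TBV), quadratic-age models compared by AIC, sex-stratified
age models, age x sex interaction models, the normalized left-right asymmetry
index 2(L - R)/(L + R) with its own regression models (main-effects with TBV,
and three-way interaction without TBV), 5-year age-subgroup regressions, and
paired / Welch t-tests.

Sex is coded female = 0, male = 1, so a negative sex coefficient means lower
values in males.  Age enters raw (not centred) in quadratic models; the
design condition number is logged.  Significance thresholds follow plain
Bonferroni over the 10 FD measures (alpha = .05/10 = .005), the 5 asymmetry
measures (.05/5 = .01), and the 20 per-sex regressions (.05/20 = .0025).

Model fitting is delegated to statsmodels OLS; AIC is reported in the
R convention (parameter count includes the residual variance), so only AIC
*differences* between models fitted to identical rows are meaningful, and
:func:`compare_models_aic` enforces identical rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

# Bonferroni-corrected significance thresholds
ALPHA_FD_MODELS = 0.05 / 10    # age/sex/asymmetry effects on the 10 FD measures
ALPHA_AI_MODELS = 0.05 / 5     # age and sex effects on the 5 asymmetry measures
ALPHA_PER_SEX = 0.05 / 20      # per-sex simple regressions (10 measures x 2 sexes)

#: extreme-outlier fence half-width in IQR units
OUTLIER_IQR_MULTIPLIER = 3.0

#: the 10 FD measure columns in canonical order
FD_COLUMNS = ("fd_lh", "fd_rh", "fd_lf", "fd_rf", "fd_lt", "fd_rt",
              "fd_lp", "fd_rp", "fd_lo", "fd_ro")

#: left/right FD column pair per region
REGION_PAIRS: dict[str, tuple[str, str]] = {
    "hemisphere": ("fd_lh", "fd_rh"),
    "frontal": ("fd_lf", "fd_rf"),
    "temporal": ("fd_lt", "fd_rt"),
    "parietal": ("fd_lp", "fd_rp"),
    "occipital": ("fd_lo", "fd_ro"),
}

#: default age subgrouping: seven 5-year bins spanning 45-80
AGE_BIN_EDGES = tuple(range(45, 85, 5))


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


class DegenerateTestError(ValueError):
    """A test statistic is undefined (zero variance)."""


# ---------------------------------------------------------------------------
# asymmetry index

def asymmetry_index(left_fd, right_fd):
    """Normalized asymmetry 2(L - R)/(L + R).

    Positive values denote leftward (left > right) asymmetry.  Accepts
    scalars or arrays; the denominator must be positive.
    """
    left = np.asarray(left_fd, dtype=float)
    right = np.asarray(right_fd, dtype=float)
    denom = left + right
    valid = ~np.isnan(denom)
    if np.any(denom[valid] <= 0):
        raise ValueError("asymmetry index requires left + right > 0")
    out = 2.0 * (left - right) / denom
    return float(out) if out.ndim == 0 else out


def add_asymmetry_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append an ``ai_<region>`` column per L/R region pair."""
    out = table.copy()
    for region, (lcol, rcol) in REGION_PAIRS.items():
        out[f"ai_{region}"] = asymmetry_index(out[lcol].to_numpy(), out[rcol].to_numpy())
    return out


# ---------------------------------------------------------------------------
# outlier screening

def remove_extreme_outliers(
    table: pd.DataFrame,
    columns: tuple[str, ...] = FD_COLUMNS,
    multiplier: float = OUTLIER_IQR_MULTIPLIER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank extreme outliers per measure; keep the subject's other measures.

    A value is extreme when outside [Q1 - m*IQR, Q3 + m*IQR] for its column
    (quartiles by linear interpolation).  Returns the filtered table (outliers
    set to NaN) and a removal log with one row per removed data point
    (subject, measure, value).
    """
    if table.empty:
        raise ValueError("table is empty")
    out = table.copy()
    records = []
    for col in columns:
        vals = out[col]
        clean = vals.dropna()
        if clean.empty:
            continue
        q1, q3 = clean.quantile(0.25), clean.quantile(0.75)
        iqr = q3 - q1
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        bad = (vals < lo) | (vals > hi)
        for idx in out.index[bad.fillna(False)]:
            subject = out.at[idx, "id"] if "id" in out.columns else idx
            records.append({"subject": subject, "measure": col, "value": out.at[idx, col]})
        out.loc[bad.fillna(False), col] = np.nan
    log = pd.DataFrame(records, columns=["subject", "measure", "value"])
    logger.info("extreme outlier removal: %d data points blanked", len(log))
    return out, log


# ---------------------------------------------------------------------------
# regression machinery

@dataclass(frozen=True)
class Term:
    estimate: float
    se: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: named coefficients, AIC, adjusted R^2.

    ``aic`` uses the R convention (Gaussian likelihood; the parameter count
    includes intercept and residual variance).  ``row_key`` fingerprints the
    exact rows used so model comparisons can enforce identical data.
    """

    response: str
    terms: dict[str, Term]
    intercept: Term
    aic: float
    adj_r_squared: float
    n_used: int
    row_key: int = field(repr=False, default=0)

    def term_names(self) -> tuple[str, ...]:
        return tuple(self.terms)


def _fit_ols(df: pd.DataFrame, response: str, regressors: list[str]) -> RegressionResult:
    cols = [response] + regressors
    data = df[cols].dropna()
    if len(data) <= len(regressors) + 1:
        raise ValueError(
            f"too few complete rows ({len(data)}) to fit {response} ~ {regressors}"
        )
    X = sm.add_constant(data[regressors].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"design for {response} ~ {regressors} is rank deficient"
        )
    y = data[response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    cond = np.linalg.cond(X)
    if cond > 1e8:
        logger.debug("design condition number %.3g for %s ~ %s", cond, response, regressors)
    names = ["const"] + regressors
    terms = {
        name: Term(float(res.params[i]), float(res.bse[i]), float(res.pvalues[i]))
        for i, name in enumerate(names)
    }
    row_key = int(pd.util.hash_pandas_object(data.index).sum())
    return RegressionResult(
        response=response,
        terms={k: v for k, v in terms.items() if k != "const"},
        intercept=terms["const"],
        aic=float(res.aic) + 2.0,  # R convention: count the residual variance
        adj_r_squared=float(res.rsquared_adj),
        n_used=int(res.nobs),
        row_key=row_key,
    )


def fit_fd_model(
    table: pd.DataFrame, response: str, include_quadratic: bool = False
) -> RegressionResult:
    """FD ~ age (+ age^2) + sex + TBV, complete cases for the involved columns."""
    df = table.copy()
    regressors = ["age"]
    if include_quadratic:
        df["age2"] = df["age"] ** 2
        regressors.append("age2")
    regressors += ["sex", "tbv"]
    return _fit_ols(df, response, regressors)


@dataclass(frozen=True)
class ModelComparison:
    aic_linear: float
    aic_quadratic: float
    preferred: str  # "linear" | "quadratic"

    @property
    def delta_aic(self) -> float:
        return self.aic_linear - self.aic_quadratic


def compare_models_aic(linear: RegressionResult, quadratic: RegressionResult) -> ModelComparison:
    """Min-AIC preference between nested age models fitted to identical rows.

    Ties prefer the simpler (linear) model.  ``delta_aic`` (linear minus
    quadratic) is exposed so callers may apply a >= 2 materiality rule.
    """
    if linear.response != quadratic.response:
        raise ValueError(
            f"model responses differ: {linear.response} vs {quadratic.response}"
        )
    if linear.n_used != quadratic.n_used or linear.row_key != quadratic.row_key:
        raise ValueError("models were not fitted on identical rows")
    preferred = "quadratic" if quadratic.aic < linear.aic else "linear"
    return ModelComparison(linear.aic, quadratic.aic, preferred)


def fit_sex_stratified(
    table: pd.DataFrame, response: str, min_n: int = 10
) -> tuple[RegressionResult | None, RegressionResult | None]:
    """Per-sex fits of FD ~ age + TBV; returns (female, male).

    A stratum with fewer than ``min_n`` complete rows is returned as None
    (flagged in the log) while the other stratum is still fitted.
    """
    results: list[RegressionResult | None] = []
    for code, name in ((0, "female"), (1, "male")):
        stratum = table[table["sex"] == code]
        complete = stratum[[response, "age", "tbv"]].dropna()
        if len(complete) < min_n:
            logger.warning("%s stratum for %s has n=%d < %d; skipped",
                           name, response, len(complete), min_n)
            results.append(None)
        else:
            results.append(_fit_ols(stratum, response, ["age", "tbv"]))
    return results[0], results[1]


def fit_interaction_model(table: pd.DataFrame, response: str) -> RegressionResult:
    """FD ~ age + sex + age:sex + TBV; the interaction p targets alpha .005."""
    df = table.copy()
    df["age_sex"] = df["age"] * df["sex"]
    return _fit_ols(df, response, ["age", "sex", "age_sex", "tbv"])


def fit_asymmetry_model(
    table: pd.DataFrame, region: str, include_tbv: bool = True
) -> RegressionResult:
    """AI ~ age + sex (+ TBV); age/sex effects on asymmetry, alpha .01."""
    df = table if f"ai_{region}" in table.columns else add_asymmetry_columns(table)
    regressors = ["age", "sex"] + (["tbv"] if include_tbv else [])
    return _fit_ols(df, f"ai_{region}", regressors)


def fit_threeway_asymmetry_model(
    table: pd.DataFrame, region: str, side: str = "left", include_tbv: bool = False
) -> RegressionResult:
    """One side's FD ~ age + sex + AI + all two-way + age:sex:AI interactions.

    The subject-level asymmetry index of the region pair enters as a
    regressor; TBV is excluded by default from this model.
    """
    if region not in REGION_PAIRS:
        raise ValueError(f"unknown region {region!r}; expected one of {sorted(REGION_PAIRS)}")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    df = table if f"ai_{region}" in table.columns else add_asymmetry_columns(table)
    df = df.copy()
    response = REGION_PAIRS[region][0 if side == "left" else 1]
    ai = f"ai_{region}"
    if df[ai].nunique(dropna=True) <= 1:
        raise SingularDesignError(f"{ai} is constant; three-way design is singular")
    df["age_sex"] = df["age"] * df["sex"]
    df["age_ai"] = df["age"] * df[ai]
    df["sex_ai"] = df["sex"] * df[ai]
    df["age_sex_ai"] = df["age"] * df["sex"] * df[ai]
    regressors = ["age", "sex", ai, "age_sex", "age_ai", "sex_ai", "age_sex_ai"]
    if include_tbv:
        regressors.append("tbv")
    return _fit_ols(df, response, regressors)


# ---------------------------------------------------------------------------
# age subgroups

@dataclass(frozen=True)
class SubgroupResult:
    age_lo: int
    age_hi: int
    n: int
    result: RegressionResult | None  # None when the bin was too small to fit


def age_subgroup_analysis(
    table: pd.DataFrame,
    response: str,
    bin_edges: tuple[int, ...] = AGE_BIN_EDGES,
    min_n: int = 10,
) -> list[SubgroupResult]:
    """Per 5-year age bin, fit FD ~ age + sex + TBV.

    Bins are half-open [lo, hi) except the final bin which is closed, so a
    subject aged exactly 50 falls in the 50-55 bin and one aged exactly 80 in
    the last.  Bins with fewer than ``min_n`` complete rows are flagged and
    skipped (result None).
    """
    out: list[SubgroupResult] = []
    for i in range(len(bin_edges) - 1):
        lo, hi = bin_edges[i], bin_edges[i + 1]
        last = i == len(bin_edges) - 2
        sel = (table["age"] >= lo) & ((table["age"] <= hi) if last else (table["age"] < hi))
        sub = table[sel]
        n = len(sub[[response, "age", "sex", "tbv"]].dropna())
        if n < min_n:
            logger.warning("age bin [%d, %d%s has n=%d < %d; skipped",
                           lo, hi, "]" if last else ")", n, min_n)
            out.append(SubgroupResult(lo, hi, n, None))
            continue
        out.append(SubgroupResult(lo, hi, n, _fit_ols(sub, response, ["age", "sex", "tbv"])))
    return out


# ---------------------------------------------------------------------------
# t-tests

def paired_t(left, right) -> tuple[float, float, str]:
    """Classical paired t-test on L/R pairs; returns (t, p, direction).

    ``direction`` is "leftward" when mean(L - R) > 0, else "rightward".
    Raises :class:`DegenerateTestError` when the differences have zero
    variance (including identical vectors).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1D vectors")
    if len(left) < 3:
        raise ValueError(f"paired t-test needs n >= 3, got {len(left)}")
    diff = left - right
    if np.ptp(diff) == 0:
        raise DegenerateTestError("differences are constant; t is undefined")
    t, p = stats.ttest_rel(left, right)
    direction = "leftward" if diff.mean() > 0 else "rightward"
    return float(t), float(p), direction


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Two-sample t with unequal variances (Welch-Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch t-test needs n >= 2 per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
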
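"""Statistical verification of FNN-selected characteristics.

Three tools: adjusted logistic odds ratios for a selected characteristic
(case vs healthy control) under a ladder of adjustment sets; signed
correlation ratios (point-biserial correlations) between a continuous
characteristic and a binary habit; and baseline-characteristics group
comparisons (pooled-variance t test for continuous rows, Pearson chi-square
without continuity correction for categorical rows).

Adjustment ladder:

    model 1  unadjusted
    model 2  age, drinking habit, smoking habit
    model 3  model 2 + BMI, SBP, DBP, triglycerides, HDL, fasting glucose
    model 4  model 3 + exercise habit

The "doubling" transform replaces a positive predictor by its base-2
logarithm, so the odds ratio is per doubling of the raw value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AdjustedORResult",
    "CorrelationResult",
    "ADJUSTMENT_SETS",
    "logistic_or",
    "correlation_eta",
    "group_compare",
    "characteristics_table",
]

ADJUSTMENT_SETS: dict[int, list[str]] = {
    1: [],
    2: ["age", "alcohol", "smoking"],
    3: ["age", "alcohol", "smoking", "bmi", "sbp", "dbp", "tg", "hdl",
        "glucose"],
    4: ["age", "alcohol", "smoking", "bmi", "sbp", "dbp", "tg", "hdl",
        "glucose", "exercise"],
}


@dataclass
class AdjustedORResult:
    predictor: str
    transform: str
    model_id: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    penalized: bool = False

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor, "transform": self.transform,
            "model": self.model_id, "or": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p_value, "n": self.n, "penalized": self.penalized,
        }


@dataclass
class CorrelationResult:
    continuous: str
    binary: str
    n: int
    eta: float
    p_value: float


def _transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return x
    if transform == "doubling":
        if np.any(x <= 0):
            raise ValueError("doubling transform requires positive values")
        return np.log2(x)
    raise ValueError(f"unknown transform {transform!r}")


def logistic_or(data: pd.DataFrame, labels: pd.Series, predictor: str,
                transform: str = "identity", model_id: int = 1,
                extra_covariates: list[str] | None = None,
                scale: float = 1.0) -> AdjustedORResult:
    """Maximum-likelihood logistic odds ratio of case (vs healthy control)
    per ``scale`` units of the (possibly transformed) predictor.

    Complete-case over predictor + adjustment set; Wald 95% CI and p-value.
    Under perfect separation the fit falls back to an L2-penalized logistic
    regression (point estimate only, CI/p set to NaN, flagged).
    """
    covars = list(ADJUSTMENT_SETS[model_id]) + list(extra_covariates or [])
    keep = labels.isin(["case", "healthy_control"])
    cols = [predictor] + covars
    sub = data.loc[keep, cols].dropna()
    y = (labels.loc[sub.index] == "case").astype(float).to_numpy()
    x = _transform(sub[predictor].to_numpy(dtype=float), transform) / scale
    X = sm.add_constant(
        np.column_stack([x] + [sub[c].to_numpy(dtype=float) for c in covars]),
        has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 1e4:
            raise np.linalg.LinAlgError("separation")
        beta, se = res.params[1], res.bse[1]
        or_, lo, hi = np.exp(beta), np.exp(beta - 1.959964 * se), \
            np.exp(beta + 1.959964 * se)
        p = res.pvalues[1]
        penalized = False
    except Exception:
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X[:, 1:], y)
        or_, lo, hi, p = float(np.exp(clf.coef_[0][0])), np.nan, np.nan, np.nan
        penalized = True
    return AdjustedORResult(
        predictor=predictor, transform=transform, model_id=model_id,
        odds_ratio=float(or_), ci_low=float(lo), ci_high=float(hi),
        p_value=float(p), n=len(sub), penalized=penalized)


def correlation_eta(values, groups, names: tuple[str, str] = ("x", "g"),
                    ) -> CorrelationResult:
    """Signed correlation ratio for a binary grouping.

    Computed as the point-biserial (Pearson) correlation of the values with
    the 0/1 indicator: positive when the group-present mean is higher; the
    magnitude equals the classical correlation ratio η for two groups.  p is
    the exact t transform with n−2 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(g))
    x, g = x[ok], g[ok]
    if len(np.unique(g)) != 2:
        raise ValueError("grouping must take exactly two values")
    if np.std(x) == 0:
        raise ValueError("continuous values are constant")
    g01 = (g == g.max()).astype(float)
    r, p = stats.pearsonr(x, g01)
    return CorrelationResult(continuous=names[0], binary=names[1],
                             n=len(x), eta=float(r), p_value=float(p))


def group_compare(a, b, kind: str = "continuous",
                  pooled: bool = True) -> dict:
    """Two-group comparison for one characteristics-table row.

    continuous: ``a``/``b`` are the raw values of each group; pooled-variance
    Student t by default (Welch with ``pooled=False``); summary mean ± SD.
    categorical: ``a``/``b`` are (n_positive, n_total) per group; Pearson
    chi-square on the 2×2 without continuity correction; summary n (%).  A
    table with an all-zero column (e.g. 100% positive in both groups) has
    chi-square 0 and p = 1 by convention.
    """
    if kind == "continuous":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both groups must be nonempty")
        t, p = stats.ttest_ind(a, b, equal_var=pooled)
        return {
            "n": (len(a), len(b)),
            "summary": ((a.mean(), a.std(ddof=1)), (b.mean(), b.std(ddof=1))),
            "statistic": float(t), "p": float(p),
        }
    if kind == "categorical":
        (ka, na), (kb, nb) = a, b
        if na == 0 or nb == 0:
            raise ValueError("both groups must be nonempty")
        table = np.array([[ka, na - ka], [kb, nb - kb]], dtype=float)
        if np.any(table.sum(axis=0) == 0):
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return {
            "n": (na, nb),
            "summary": ((ka, 100.0 * ka / na), (kb, 100.0 * kb / nb)),
            "statistic": float(chi2), "p": float(p),
        }
    raise ValueError(f"unknown kind {kind!r}")


_BINARY_CHARACTERISTICS = ["alcohol", "smoking"]
_CONTINUOUS_CHARACTERISTICS = [
    "age", "height", "weight", "bmi", "sbp", "dbp", "tc", "tg", "hdl",
    "glucose",
]


def characteristics_table(data: pd.DataFrame, labels: pd.Series,
                          group_a: str = "case",
                          group_b: str = "healthy_control") -> pd.DataFrame:
    """Baseline-characteristics comparison table between two label groups.

    One row per characteristic: complete-case n per group, mean ± SD (or
    n, %) per group, and the group-comparison p-value.  Empty cohorts give
    an empty table.
    """
    da = data.loc[labels == group_a]
    db = data.loc[labels == group_b]
    rows = []
    if len(da) == 0 or len(db) == 0:
        return pd.DataFrame(columns=[
            "characteristic", "kind", "n_a", "summary_a", "n_b", "summary_b",
            "p"])
    for col in _CONTINUOUS_CHARACTERISTICS:
        if col not in data.columns:
            continue
        res = group_compare(da[col].to_numpy(float), db[col].to_numpy(float),
                            "continuous")
        (ma, sa), (mb, sb) = res["summary"]
        rows.append((col, "continuous", res["n"][0],
                     f"{ma:.1f} ± {sa:.1f}", res["n"][1],
                     f"{mb:.1f} ± {sb:.1f}", res["p"]))
    for col in _BINARY_CHARACTERISTICS:
        if col not in data.columns:
            continue
        xa, xb = da[col].dropna(), db[col].dropna()
        res = group_compare((int(xa.sum()), len(xa)),
                            (int(xb.sum()), len(xb)), "categorical")
        (ka, pa), (kb, pb) = res["summary"]
        rows.append((col, "categorical", res["n"][0],
                     f"{ka} ({pa:.1f}%)", res["n"][1],
                     f"{kb} ({pb:.1f}%)", res["p"]))
    return pd.DataFrame(rows, columns=[
        "characteristic", "kind", "n_a", "summary_a", "n_b", "summary_b", "p"])
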
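"""Cross-validated accuracy, null baseline, and forward input selection.

The accuracy statistic weights the training-set and validation-set correct
fractions 1:2,

    Accuracy(%) = 100 · [ (correct_train / n_train) · 1/3
                         + (correct_test / n_test) · 2/3 ],

computed per fold of a fivefold cross-validation and averaged over folds.
The null baseline is the accuracy of predicting every subject as the
majority class.  Forward ("parameter-increasing") selection screens each
candidate alone, keeps the best, then pairs it with each remaining
candidate; every candidate set is evaluated on its own complete-case subset,
so subject counts differ across stages exactly as they do when missingness
varies by characteristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fnn import TrainingConfig, correct_mask, fit_fnn, forward

__all__ = [
    "CVPlan",
    "SelectionResult",
    "weighted_accuracy",
    "null_baseline",
    "make_cv_plan",
    "cv_accuracy",
    "comparator_accuracy",
    "forward_select",
    "complete_cases",
]


def weighted_accuracy(correct_train: int, n_train: int,
                      correct_test: int, n_test: int) -> float:
    """The 1/3-train + 2/3-test weighted percent-correct."""
    if n_train <= 0 or n_test <= 0:
        raise ValueError("set sizes must be positive")
    if not (0 <= correct_train <= n_train and 0 <= correct_test <= n_test):
        raise ValueError("correct counts must lie in [0, n]")
    return 100.0 * (correct_train / n_train / 3.0
                    + 2.0 * correct_test / n_test / 3.0)


def null_baseline(n_case: int, n_control: int) -> float:
    """Majority-class accuracy in percent, rounded to 2 decimals for
    reporting (e.g. 57 vs 99 → 63.46)."""
    if n_case < 0 or n_control < 0:
        raise ValueError("counts must be non-negative")
    total = n_case + n_control
    if total == 0:
        raise ValueError("at least one subject required")
    return round(100.0 * max(n_case, n_control) / total, 2)


@dataclass(frozen=True)
class CVPlan:
    """A seeded shuffle split into near-equal folds (sizes differ by ≤1)."""

    order: np.ndarray
    folds: list[np.ndarray]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_plan(n_subjects: int, seed: int, n_folds: int = 5) -> CVPlan:
    """Randomly arrange ``n_subjects`` positions and cut them into
    ``n_folds`` contiguous near-equal folds; deterministic under ``seed``."""
    if n_subjects < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {n_subjects}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    folds = [f.copy() for f in np.array_split(order, n_folds)]
    return CVPlan(order=order, folds=folds)


def complete_cases(data: pd.DataFrame, inputs: list[str]) -> pd.DataFrame:
    """Rows with every named input observed."""
    return data.dropna(subset=list(inputs))


def _targets(labels: pd.Series) -> np.ndarray:
    t = np.where(labels.to_numpy() == "case", 1.0, -1.0)
    return t


def _fold_counts(y_train, t_train, y_test, t_test) -> float:
    return weighted_accuracy(
        int(correct_mask(y_train, t_train).sum()), len(t_train),
        int(correct_mask(y_test, t_test).sum()), len(t_test))


def cv_accuracy(data: pd.DataFrame, inputs: list[str], labels: pd.Series,
                plan: CVPlan, config: TrainingConfig | None = None,
                ) -> tuple[float, list[float]]:
    """Mean weighted accuracy of the FNN over the plan's folds.

    For each fold: train on the other folds, score correctness (y* strictly
    on the target side of 0) on training and held-out subjects, combine with
    :func:`weighted_accuracy`.  Returns (mean, per-fold values).
    """
    t = _targets(labels)
    per_fold = []
    for i, test_idx in enumerate(plan.folds):
        train_idx = np.concatenate(
            [f for j, f in enumerate(plan.folds) if j != i])
        t_tr, t_te = t[train_idx], t[test_idx]
        if len(np.unique(t_tr)) < 2 or len(np.unique(t_te)) < 2:
            raise ValueError(f"fold {i} lacks both classes "
                             f"(train {len(t_tr)}, test {len(t_te)} subjects)")
        model = fit_fnn(data.iloc[train_idx], inputs, t_tr, config)
        y_tr = forward(model, data.iloc[train_idx])
        y_te = forward(model, data.iloc[test_idx])
        per_fold.append(_fold_counts(y_tr, t_tr, y_te, t_te))
    return float(np.mean(per_fold)), per_fold


def comparator_accuracy(data: pd.DataFrame, inputs: list[str],
                        labels: pd.Series, plan: CVPlan,
                        kind: str) -> tuple[float, bool]:
    """Weighted accuracy of a multiple linear or logistic regression on the
    same folds as the FNN run.

    linear: least squares on targets ±1, case iff fitted value > 0;
    logistic: maximum likelihood, case iff fitted probability > 0.5 (scored
    via y* = p − 0.5).  Returns (mean accuracy, penalized-fallback flag);
    the flag is set when perfect separation forces an L2-penalized logistic
    fit for some fold.
    """
    if kind not in ("linear", "logistic"):
        raise ValueError(f"unknown comparator {kind!r}")
    t = _targets(labels)
    X = data[list(inputs)].to_numpy(dtype=float) if inputs else \
        np.empty((len(data), 0))
    per_fold, flagged = [], False
    for i, test_idx in enumerate(plan.folds):
        train_idx = np.concatenate(
            [f for j, f in enumerate(plan.folds) if j != i])
        Xtr = sm.add_constant(X[train_idx], has_constant="add")
        Xte = sm.add_constant(X[test_idx], has_constant="add")
        t_tr, t_te = t[train_idx], t[test_idx]
        if kind == "linear":
            beta, *_ = np.linalg.lstsq(Xtr, t_tr, rcond=None)
            y_tr, y_te = Xtr @ beta, Xte @ beta
        else:
            y01 = (t_tr > 0).astype(float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y01, Xtr).fit(disp=0, maxiter=200)
                    if not np.all(np.isfinite(res.params)) or \
                            np.abs(res.params).max() > 1e4:
                        raise np.linalg.LinAlgError("separation")
                    p_tr = res.predict(Xtr)
                    p_te = res.predict(Xte)
            except Exception:
                from sklearn.linear_model import LogisticRegression
                clf = LogisticRegression(C=1.0, max_iter=1000)
                clf.fit(Xtr, y01)
                p_tr = clf.predict_proba(Xtr)[:, 1]
                p_te = clf.predict_proba(Xte)[:, 1]
                flagged = True
            y_tr, y_te = p_tr - 0.5, p_te - 0.5
        per_fold.append(_fold_counts(y_tr, t_tr, y_te, t_te))
    return float(np.mean(per_fold)), flagged


@dataclass
class SelectionResult:
    """One stage of the forward selection (one row of the results table)."""

    inputs: list[str]
    n_case: int
    n_control: int
    baseline: float
    fnn_accuracy: float
    linear_accuracy: float
    logistic_accuracy: float
    logistic_fallback: bool = False
    candidate_scores: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "n_case": self.n_case,
            "n_control": self.n_control,
            "baseline_pct": self.baseline,
            "fnn_accuracy_pct": self.fnn_accuracy,
            "linear_accuracy_pct": self.linear_accuracy,
            "logistic_accuracy_pct": self.logistic_accuracy,
            "logistic_fallback": self.logistic_fallback,
            "candidate_scores": dict(self.candidate_scores),
        }


def _evaluate_set(data: pd.DataFrame, labels: pd.Series, inputs: list[str],
                  seed: int, config, n_folds: int):
    cc = complete_cases(data, inputs)
    lab = labels.loc[cc.index]
    n_case = int((lab == "case").sum())
    n_control = int((lab == "healthy_control").sum())
    if n_case < 2 or n_control < 2:
        return None
    try:
        plan = make_cv_plan(len(cc), seed, n_folds)
        acc, _ = cv_accuracy(cc, inputs, lab, plan, config)
    except ValueError:
        return None
    return cc, lab, plan, n_case, n_control, acc


def forward_select(data: pd.DataFrame, labels: pd.Series,
                   candidates: list[str], k_max: int = 2, seed: int = 0,
                   config: TrainingConfig | None = None,
                   n_folds: int = 5) -> list[SelectionResult]:
    """Greedy parameter-increasing selection over the candidate inputs.

    ``data``/``labels`` should already be restricted to case and
    healthy-control subjects.  Stage s evaluates the stage-(s−1) winner
    extended by each remaining candidate; ties break toward the earlier
    candidate in the screening order.  Each input set is filtered to its own
    complete cases, so n_case/n_control shrink as inputs accumulate.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    keep = (labels == "case") | (labels == "healthy_control")
    data = data.loc[keep[keep].index]
    labels = labels.loc[data.index]

    selected: list[str] = []
    results: list[SelectionResult] = []
    remaining = list(candidates)
    for _stage in range(min(k_max, len(candidates))):
        best = None
        scores: dict[str, float] = {}
        for cand in remaining:
            inputs = selected + [cand]
            ev = _evaluate_set(data, labels, inputs, seed, config, n_folds)
            if ev is None:
                continue
            scores[cand] = ev[5]
            if best is None or ev[5] > best[1][5]:
                best = (cand, ev)
        if best is None:
            if not results:
                raise ValueError("no usable candidate input sets")
            break
        cand, (cc, lab, plan, n_case, n_control, acc) = best
        selected.append(cand)
        remaining.remove(cand)
        lin, _ = comparator_accuracy(cc, selected, lab, plan, "linear")
        log, fb = comparator_accuracy(cc, selected, lab, plan, "logistic")
        results.append(SelectionResult(
            inputs=list(selected),
            n_case=n_case,
            n_control=n_control,
            baseline=null_baseline(n_case, n_control),
            fnn_accuracy=acc,
            linear_accuracy=lin,
            logistic_accuracy=log,
            logistic_fallback=fb,
            candidate_scores=scores,
        ))
    return results
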
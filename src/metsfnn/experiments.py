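"""Repeated-seed experiment harness.

Bundles the full analysis chain (generate → label → forward-select →
extract rule) for one seed, and a repeater that measures how often the
embedded γ-GTP × WBC risk combination is recovered across seeds — the
package's main end-to-end validation of the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cohort as sc
from .criteria import assign_cohort_labels
from .fnn import TrainingConfig, fit_fnn
from .rules import FuzzyRuleMatrix, build_rule_matrix
from .selection import SelectionResult, complete_cases, forward_select

__all__ = ["RecoveryRun", "run_single_recovery", "run_recovery_experiment"]


@dataclass
class RecoveryRun:
    seed: int
    selection: list[SelectionResult]
    recovered: bool                      # final pair == {ggtp, wbc}
    rule_matrix: FuzzyRuleMatrix | None  # None unless a 2-input model fit
    high_high_dominant: bool             # largest Wf and case fraction in (1,1)


def _high_high_dominates(matrix: FuzzyRuleMatrix) -> bool:
    weights = {k: c["weight"] for k, c in matrix.cells.items()}
    if max(weights, key=weights.get) != (1, 1):
        return False
    frac = {}
    for k, c in matrix.cells.items():
        total = c["n_case"] + c["n_control"]
        frac[k] = c["n_case"] / total if total else -1.0
    return max(frac, key=frac.get) == (1, 1)


def run_single_recovery(seed: int, n_subjects: int = 2000,
                        config: TrainingConfig | None = None) -> RecoveryRun:
    """Default original-study cohort → labels → forward selection → rule."""
    spec = sc.original_spec(n_subjects=n_subjects, seed=seed)
    baseline, followup = sc.generate_cohort(spec)
    labels = assign_cohort_labels(baseline, followup)
    cfg = config or TrainingConfig(seed=seed)
    selection = forward_select(baseline, labels, sc.CANDIDATE_COLUMNS,
                               k_max=2, seed=seed, config=cfg)
    final = selection[-1]
    recovered = set(final.inputs) == {"ggtp", "wbc"}

    matrix = None
    dominant = False
    if len(final.inputs) == 2:
        keep = labels.isin(["case", "healthy_control"])
        data = complete_cases(baseline.loc[keep], final.inputs)
        lab = labels.loc[data.index]
        targets = pd.Series(1.0, index=data.index).where(
            lab == "case", -1.0).to_numpy()
        # order inputs so the matrix is (γ-GTP, WBC) when recovered
        inputs = sorted(final.inputs,
                        key=lambda c: sc.CANDIDATE_COLUMNS.index(c))
        model = fit_fnn(data, inputs, targets, cfg)
        matrix = build_rule_matrix(model, data, lab)
        dominant = _high_high_dominates(matrix)
    return RecoveryRun(seed=seed, selection=selection, recovered=recovered,
                       rule_matrix=matrix, high_high_dominant=dominant)


def run_recovery_experiment(n_seeds: int = 20, base_seed: int = 0,
                            n_subjects: int = 2000) -> list[RecoveryRun]:
    """One :func:`run_single_recovery` per seed ``base_seed + i``."""
    return [run_single_recovery((base_seed + i) % (2 ** 31), n_subjects)
            for i in range(n_seeds)]
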
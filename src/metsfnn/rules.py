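"""Fuzzy-rule extraction: thresholds, 2×2 cell counts, rule weights.

A trained two-input network is summarized as a matrix: for each input a
crisp low/high threshold (the raw value at which the "high" membership
crosses 0.5), and for each low/high cell the number of cases, the number of
controls, and the rule weight Wf.  The matrix is the human-readable form of
the learned rule, e.g. "high γ-GTP and high WBC → case, weight 1.07".
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fnn import FNNModel, MembershipPair, membership

__all__ = [
    "crossover_threshold",
    "assign_cell",
    "FuzzyRuleMatrix",
    "build_rule_matrix",
    "export_scatter",
]


def crossover_threshold(pair: MembershipPair, mean: float, sd: float) -> float:
    """Raw-units input value where f_high = 0.5 (standardized Wc/Wg mapped
    back through the training mean/sd)."""
    if pair.wg_high == 0:
        raise ValueError("flat membership: wg_high must be nonzero")
    return mean + sd * (pair.wc_high / pair.wg_high)


def model_thresholds(model: FNNModel) -> dict[str, float]:
    out = {}
    for j, name in enumerate(model.inputs):
        thr = crossover_threshold(model.pairs[j], model.means[j], model.sds[j])
        if name in model.log_inputs:
            thr = float(np.exp(thr))
        out[name] = float(thr)
    return out


def assign_cell(values, model: FNNModel, fuzzy: bool = False) -> tuple[int, ...]:
    """Low/high cell of one subject: high (1) iff the raw value is at or
    above the crossover threshold.  With ``fuzzy=True`` each input instead
    takes the side whose membership grade is larger."""
    thr = model_thresholds(model)
    if isinstance(values, pd.Series):
        values = [values[name] for name in model.inputs]
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("assign_cell requires complete cases")
    if not fuzzy:
        return tuple(int(v >= thr[name])
                     for v, name in zip(values, model.inputs))
    z = model.standardize(values.reshape(1, -1))[0]
    cell = []
    for j, p in enumerate(model.pairs):
        lo = membership(z[j], p.wc_low, p.wg_low)
        hi = membership(z[j], p.wc_high, p.wg_high)
        cell.append(int(hi >= lo))
    return tuple(cell)


@dataclass
class FuzzyRuleMatrix:
    """Thresholds plus per-cell (n_case, n_control, Wf)."""

    inputs: list[str]
    thresholds: dict[str, float]
    cells: dict[tuple[int, ...], dict]

    def to_json(self) -> str:
        d = {
            "inputs": self.inputs,
            "thresholds": self.thresholds,
            "cells": {"/".join("high" if s else "low" for s in k): v
                      for k, v in self.cells.items()},
        }
        return json.dumps(d, indent=2)

    def render_text(self) -> str:
        """Plain-text matrix in the familiar 2×2 layout (two inputs only):
        rows = input 1 low/high, columns = input 2 low/high; each cell shows
        'n_case / n_control' over the rule weight."""
        if len(self.inputs) != 2:
            raise ValueError("text rendering needs exactly two inputs")
        a, b = self.inputs
        lines = [f"rows: {a} (threshold {self.thresholds[a]:.4g}), "
                 f"cols: {b} (threshold {self.thresholds[b]:.4g})"]
        header = f"{'':>10s} | {'low ' + b:^22s} | {'high ' + b:^22s}"
        lines.append(header)
        lines.append("-" * len(header))
        for sa, row in ((0, "low"), (1, "high")):
            cells = []
            for sb in (0, 1):
                c = self.cells[(sa, sb)]
                cells.append(f"{c['n_case']:>4d} case /{c['n_control']:>5d} ctrl "
                             f"Wf={c['weight']:+.3f}")
            lines.append(f"{row + ' ' + a:>10s} | {cells[0]} | {cells[1]}")
        return "\n".join(lines)


def build_rule_matrix(model: FNNModel, data: pd.DataFrame,
                      labels: pd.Series, fuzzy: bool = False) -> FuzzyRuleMatrix:
    """Count cases and controls per low/high cell and attach the rule
    weights.  Cell totals conserve the complete-case class totals."""
    X = data[model.inputs]
    if X.isna().any().any():
        raise ValueError("rule matrix requires complete cases")
    thr = model_thresholds(model)
    sides = np.column_stack([
        (X[name].to_numpy(dtype=float) >= thr[name]).astype(int)
        for name in model.inputs])
    if fuzzy:
        sides = np.array([assign_cell(row, model, fuzzy=True)
                          for row in X.to_numpy(dtype=float)])
    is_case = (labels.loc[X.index] == "case").to_numpy()
    cells = {}
    for r, combo in enumerate(model.rules):
        in_cell = np.all(sides == np.array(combo), axis=1)
        cells[combo] = {
            "n_case": int((in_cell & is_case).sum()),
            "n_control": int((in_cell & ~is_case).sum()),
            "weight": float(model.rule_weights[r]),
        }
    return FuzzyRuleMatrix(inputs=list(model.inputs), thresholds=thr,
                           cells=cells)


def export_scatter(data: pd.DataFrame, inputs: list[str],
                   labels: pd.Series) -> pd.DataFrame:
    """Complete-case (x1, x2, label) table for scatter plotting."""
    cc = data.dropna(subset=list(inputs))
    out = cc[list(inputs)].copy()
    out["label"] = labels.loc[cc.index].to_numpy()
    return out.reset_index(drop=True)
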
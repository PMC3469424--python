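"""Metabolic-syndrome classification and cohort labeling.

Implements the Japanese (JASSO) MetS definition — obesity (waist ≥85 cm, or
BMI ≥25 kg/m² when waist is unmeasured) plus any two of raised blood
pressure (SBP ≥130 or DBP ≥85), dyslipidemia (TG ≥150 or HDL <40) and
raised fasting glucose (≥110) — and the longitudinal case / healthy-control /
normal-control labeling with medication exclusion.

All boundaries are inclusive exactly as stated above.  Missing measurements
propagate as indeterminate flags (``None`` in the scalar API, ``NaN`` in the
vectorized one), which is distinct from a definite ``False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ComponentFlags",
    "component_flags",
    "is_mets",
    "component_flags_frame",
    "assign_cohort_labels",
    "LABELS",
]

LABELS = ("case", "healthy_control", "normal_control", "excluded")

# columns a year must have observed before it can certify "component-free"
_REQUIRED_FOR_FREE = ("bmi", "sbp", "dbp", "tg", "hdl", "glucose")


class UndeterminableError(ValueError):
    """Raised when a classification cannot be made from the available data."""


@dataclass(frozen=True)
class ComponentFlags:
    """Per-examination MetS component flags; ``None`` marks a flag whose
    inputs were all missing."""

    obesity: Optional[bool]
    raised_bp: Optional[bool]
    dyslipidemia: Optional[bool]
    raised_glucose: Optional[bool]

    @property
    def n_components(self) -> int:
        """Number of flags definitely present (indeterminate ≠ present)."""
        return sum(bool(f) for f in
                   (self.obesity, self.raised_bp, self.dyslipidemia,
                    self.raised_glucose))

    @property
    def determinable(self) -> bool:
        return all(f is not None for f in
                   (self.obesity, self.raised_bp, self.dyslipidemia,
                    self.raised_glucose))


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def component_flags(*, waist=None, bmi=None, sbp=None, dbp=None,
                    tg=None, hdl=None, glucose=None) -> ComponentFlags:
    """Evaluate the four component criteria for one examination.

    Obesity uses waist circumference ≥85 cm when measured, else the BMI ≥25
    fallback.  A flag is ``None`` when every measurement it depends on is
    missing.  Raises :class:`UndeterminableError` if nothing is observed.
    """
    if _isnan(waist):
        obesity = None if _isnan(bmi) else bool(bmi >= 25.0)
    else:
        obesity = bool(waist >= 85.0)

    bp_parts = [sbp >= 130.0 if not _isnan(sbp) else None,
                dbp >= 85.0 if not _isnan(dbp) else None]
    raised_bp = _any_or_none(bp_parts)

    lipid_parts = [tg >= 150.0 if not _isnan(tg) else None,
                   hdl < 40.0 if not _isnan(hdl) else None]
    dyslipidemia = _any_or_none(lipid_parts)

    raised_glucose = None if _isnan(glucose) else bool(glucose >= 110.0)

    flags = ComponentFlags(obesity, raised_bp, dyslipidemia, raised_glucose)
    if all(f is None for f in (obesity, raised_bp, dyslipidemia, raised_glucose)):
        raise UndeterminableError("no component measurement observed")
    return flags


def _any_or_none(parts):
    # "or" with indeterminates: True dominates, all-None is None,
    # None+False stays None (the missing half could have been True)
    known_true = any(p is True for p in parts)
    if known_true:
        return True
    if any(p is None for p in parts):
        return None
    return False


def is_mets(flags: ComponentFlags) -> bool:
    """Obesity plus at least two of the other three criteria."""
    if not flags.determinable:
        raise UndeterminableError("component flags are indeterminate")
    others = (flags.raised_bp, flags.dyslipidemia, flags.raised_glucose)
    return bool(flags.obesity) and sum(map(bool, others)) >= 2


# ---------------------------------------------------------------------------
# vectorized panel operations


def component_flags_frame(panel: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`component_flags` over a panel table.

    Returns a DataFrame with nullable-boolean columns ``obesity``,
    ``raised_bp``, ``dyslipidemia``, ``raised_glucose`` plus an integer
    ``n_components`` (indeterminate flags count as absent) and a boolean
    ``free_certified`` marking rows where all six component measurements are
    observed and every flag is definitely false.
    """
    def col(name):
        if name in panel.columns:
            return panel[name].astype(float)
        return pd.Series(np.nan, index=panel.index)

    waist, bmi = col("waist"), col("bmi")
    sbp, dbp = col("sbp"), col("dbp")
    tg, hdl, glu = col("tg"), col("hdl"), col("glucose")

    obesity = (waist >= 85.0).mask(waist.isna(), (bmi >= 25.0).mask(bmi.isna()))
    raised_bp = _any_or_na(sbp >= 130.0, sbp.isna(), dbp >= 85.0, dbp.isna())
    dyslip = _any_or_na(tg >= 150.0, tg.isna(), hdl < 40.0, hdl.isna())
    raised_glu = (glu >= 110.0).mask(glu.isna())

    out = pd.DataFrame({
        "obesity": obesity.astype("boolean"),
        "raised_bp": raised_bp.astype("boolean"),
        "dyslipidemia": dyslip.astype("boolean"),
        "raised_glucose": raised_glu.astype("boolean"),
    }, index=panel.index)
    out["n_components"] = out.fillna(False).sum(axis=1).astype(int)
    observed = ~(bmi.isna() | sbp.isna() | dbp.isna() | tg.isna()
                 | hdl.isna() | glu.isna())
    out["free_certified"] = observed & (out["n_components"] == 0) \
        & out.notna().all(axis=1)
    return out


def _any_or_na(a, a_na, b, b_na):
    res = (a & ~a_na) | (b & ~b_na)
    unknown = ~res & (a_na | b_na)
    return res.astype("boolean").mask(unknown)


def mets_frame(panel: pd.DataFrame) -> pd.Series:
    """Boolean Series: row definitely meets the MetS rule (indeterminate
    flags are treated as not-present, so this never over-calls MetS)."""
    f = component_flags_frame(panel)
    others = f[["raised_bp", "dyslipidemia", "raised_glucose"]].fillna(False)
    return (f["obesity"].fillna(False) & (others.sum(axis=1) >= 2)).astype(bool)


def assign_cohort_labels(baseline: pd.DataFrame,
                         followup: pd.DataFrame) -> pd.Series:
    """Label every subject as case / healthy_control / normal_control /
    excluded.

    Rules, in priority order: any medication flag (antihypertensive,
    lipid-lowering, anti-diabetic) → ``excluded``; MetS already present at
    baseline → ``excluded`` (cases must *develop* the syndrome); MetS in any
    follow-up year → ``case``; certified free of all four components at
    baseline and in every follow-up year → ``healthy_control``; otherwise
    ``normal_control``.  Subjects with no follow-up rows are ``excluded``.
    """
    labels = pd.Series("normal_control", index=baseline.index, name="label")

    meds = pd.Series(False, index=baseline.index)
    for c in ("med_antihypertensive", "med_lipid", "med_diabetic"):
        if c in baseline.columns:
            meds |= baseline[c].fillna(0).astype(float) > 0

    base_flags = component_flags_frame(baseline)
    base_mets = mets_frame(baseline)

    fu = followup.set_index("subject_id")
    fu_mets = mets_frame(fu).groupby(level=0).any()
    fu_free = component_flags_frame(fu)["free_certified"].groupby(level=0).all()
    has_fu = baseline.index.isin(fu.index)

    ever_case = fu_mets.reindex(baseline.index, fill_value=False)
    always_free = fu_free.reindex(baseline.index, fill_value=False) \
        & base_flags["free_certified"].fillna(False).astype(bool)

    labels[always_free.to_numpy()] = "healthy_control"
    labels[ever_case.to_numpy()] = "case"
    labels[~has_fu] = "excluded"
    labels[base_mets.to_numpy()] = "excluded"
    labels[meds.to_numpy()] = "excluded"
    return labels
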
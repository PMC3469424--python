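"""Synthetic cohort generator: marginals, associations, onset, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metsfnn as m
from metsfnn import cohort as sc


def test_empty_cohort():
    spec = m.original_spec(n_subjects=0, seed=0)
    base = sc.generate_baseline(spec)
    assert len(base) == 0
    fu = sc.simulate_followup(base, spec)
    assert len(fu) == 0


@pytest.mark.parametrize("bad", [
    dict(n_subjects=-1),
    dict(n_subjects=10, follow_up_years=0),
    dict(n_subjects=10, alcohol_prev=1.5),
    dict(n_subjects=10, missingness={"ggtp": 1.0}),
])
def test_spec_validation(bad):
    with pytest.raises(ValueError):
        sc.CohortSpec(**bad)


def test_negative_sd_rejected():
    with pytest.raises(ValueError):
        sc.Marginal(10.0, -1.0)


def test_marginal_means_within_three_se():
    """Generated continuous marginals track the spec targets."""
    spec = m.original_spec(n_subjects=5000, seed=3)
    base = sc.generate_baseline(spec)
    for col in ("age", "bmi", "sbp", "hdl", "glucose", "ggtp", "wbc", "tg"):
        mm = spec.marginals[col]
        se = mm.sd / np.sqrt(len(base))
        assert abs(base[col].mean() - mm.mean) < 3 * se, col


def test_zero_association_gives_null_correlation():
    """With all habit/age effects off, WBC is uncorrelated with smoking."""
    spec = m.original_spec(n_subjects=5000, seed=11).replace(
        wbc_smoking_shift=0.0, ggtp_alcohol_logshift=0.0,
        ggtp_age_logslope=0.0)
    base = sc.generate_baseline(spec)
    r = stats.pearsonr(base["wbc"], base["smoking"]).statistic
    assert abs(r) < 0.05


def test_habit_effects_raise_biomarkers():
    spec = m.original_spec(n_subjects=5000, seed=5)
    base = sc.generate_baseline(spec)
    assert base.loc[base.smoking == 1, "wbc"].mean() > \
        base.loc[base.smoking == 0, "wbc"].mean() + 500
    assert base.loc[base.alcohol == 1, "ggtp"].mean() > \
        base.loc[base.alcohol == 0, "ggtp"].mean()
    young = base.age < base.age.quantile(0.25)
    old = base.age > base.age.quantile(0.75)
    assert base.loc[old, "ggtp"].mean() > base.loc[young, "ggtp"].mean()


@pytest.mark.parametrize("make,target", [
    (m.original_spec, 16.3), (m.replication_spec, 27.3)])
def test_healthy_stratum_ggtp_means(make, target):
    """Healthy-control mean γ-GTP lands near the study values (±15%)."""
    spec = make(n_subjects=5000, seed=2)
    base, fu = m.generate_cohort(spec)
    labels = m.assign_cohort_labels(base, fu)
    mean = base.loc[labels == "healthy_control", "ggtp"].mean()
    assert abs(mean - target) / target < 0.15


def test_degenerate_incidence():
    """With the onset model switched off and no component pressure, nobody
    develops MetS through the forced pathway."""
    spec = m.original_spec(n_subjects=500, seed=1).replace(
        onset_intercept=-40.0, onset_ggtp=0.0, onset_wbc=0.0,
        onset_interaction=0.0, followup_noise_frac=1e-6,
        followup_drift={})
    base = sc.generate_baseline(spec)
    # place everyone safely under every threshold
    for col, val in [("bmi", 21.0), ("sbp", 115.0), ("dbp", 70.0),
                     ("tg", 80.0), ("hdl", 60.0), ("glucose", 90.0)]:
        base[col] = val
    fu = sc.simulate_followup(base, spec)
    from metsfnn.criteria import mets_frame
    assert not mets_frame(fu).any()


def test_interaction_incidence_matches_logistic_oracle():
    """With natural threshold crossings suppressed, quadrant-wise MetS
    incidence equals the closed-form logistic onset probability within
    binomial error."""
    spec = m.original_spec(n_subjects=5000, seed=9).replace(
        onset_intercept=-2.0, onset_ggtp=0.0, onset_wbc=0.0,
        onset_interaction=1.0, followup_noise_frac=1e-6, followup_drift={})
    base = sc.generate_baseline(spec)
    for col, val in [("bmi", 21.0), ("sbp", 115.0), ("dbp", 70.0),
                     ("tg", 80.0), ("hdl", 60.0), ("glucose", 90.0)]:
        base[col] = val
    prob = sc.onset_probability(base, spec)
    fu = sc.simulate_followup(base, spec)
    from metsfnn.criteria import mets_frame
    onset = mets_frame(fu).groupby(fu["subject_id"]).any().reindex(base.index)

    log_g = np.log(base.ggtp)
    zg = (log_g - log_g.mean()) / log_g.std()
    zw = (base.wbc - base.wbc.mean()) / base.wbc.std()
    for name, mask in [("hh", (zg > 0) & (zw > 0)),
                       ("ll", (zg < 0) & (zw < 0)),
                       ("hl", (zg > 0) & (zw < 0))]:
        p_hat = onset[mask.to_numpy()].mean()
        p_exp = prob[mask.to_numpy()].mean()
        se = np.sqrt(p_exp * (1 - p_exp) / mask.sum())
        assert abs(p_hat - p_exp) < 3 * se, name


def test_default_spec_high_high_quadrant_dominates(small_cohort):
    """Under the default onset model (positive marginals + interaction) the
    (high γ-GTP, high WBC) quadrant has more MetS onsets than (low, low)."""
    spec, base, fu, labels = small_cohort
    case = labels == "case"
    log_g = np.log(base.ggtp)
    zg = (log_g - log_g.mean()) / log_g.std()
    zw = (base.wbc - base.wbc.mean()) / base.wbc.std()
    hh = ((zg > 0) & (zw > 0)).to_numpy()
    ll = ((zg < 0) & (zw < 0)).to_numpy()
    assert case[hh].mean() > case[ll].mean()


def test_case_healthy_ratio_near_one_to_two(small_cohort):
    _, _, _, labels = small_cohort
    vc = labels.value_counts()
    ratio = vc["case"] / vc["healthy_control"]
    assert 0.3 < ratio < 0.8


def test_missingness_identity_and_rate():
    spec = m.original_spec(n_subjects=5000, seed=4)
    base = sc.generate_baseline(spec)
    unchanged = sc.inject_missingness(
        base, spec.replace(missingness={c: 0.0 for c in spec.missingness}))
    pd.testing.assert_frame_equal(unchanged, base)

    spec2 = spec.replace(missingness={"ggtp": 0.2, "wbc": 0.2})
    out = sc.inject_missingness(base, spec2)
    for col in ("ggtp", "wbc"):
        frac = out[col].isna().mean()
        assert abs(frac - 0.2) < 0.02
    # independence: complete-case fraction for the pair is the product law
    both = out[["ggtp", "wbc"]].dropna()
    assert abs(len(both) / len(out) - 0.64) < 0.03


def test_fixed_seed_bit_identical():
    spec = m.original_spec(n_subjects=400, seed=123)
    b1, f1 = m.generate_cohort(spec)
    b2, f2 = m.generate_cohort(spec)
    pd.testing.assert_frame_equal(b1, b2)
    pd.testing.assert_frame_equal(f1, f2)


def test_null_onset_strata_indistinguishable():
    """With zero onset effects the case and control γ-GTP distributions are
    KS-indistinguishable (≤2 failures at p>0.01 over 20 seeds)."""
    failures = 0
    for seed in range(20):
        spec = m.original_spec(n_subjects=2000, seed=seed).replace(
            onset_ggtp=0.0, onset_wbc=0.0, onset_interaction=0.0,
            onset_intercept=-3.0)
        base, fu = m.generate_cohort(spec)
        labels = m.assign_cohort_labels(base, fu)
        g_case = base.loc[labels == "case", "ggtp"].dropna()
        g_ctrl = base.loc[labels == "healthy_control", "ggtp"].dropna()
        if len(g_case) < 10 or len(g_ctrl) < 10:
            continue
        if stats.ks_2samp(g_case, g_ctrl).pvalue <= 0.01:
            failures += 1
    assert failures <= 2


def test_healthy_stratum_ggtp_wbc_corr_nonnegative(small_cohort):
    """Shared smoking/drinking drivers keep corr(γ-GTP, WBC) ≥ 0 among
    healthy controls."""
    spec, base, _, labels = small_cohort
    hc = base.loc[labels == "healthy_control", ["ggtp", "wbc"]].dropna()
    r = stats.pearsonr(np.log(hc.ggtp), hc.wbc).statistic
    assert r > -0.05
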
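"""Adjusted odds ratios, correlation ratios, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metsfnn as m
from metsfnn.verify import (characteristics_table, correlation_eta,
                            group_compare, logistic_or)


def _frame_from_2x2(a, b, c, d):
    """a exposed cases, b unexposed cases, c exposed ctrls, d unexposed."""
    x = [1] * a + [0] * b + [1] * c + [0] * d
    lab = ["case"] * (a + b) + ["healthy_control"] * (c + d)
    df = pd.DataFrame({"x": np.asarray(x, dtype=float)})
    return df, pd.Series(lab, index=df.index)


class TestLogisticOR:
    def test_2x2_equals_cross_product(self):
        df, labels = _frame_from_2x2(30, 20, 10, 40)
        res = logistic_or(df, labels, "x", model_id=1)
        assert res.odds_ratio == pytest.approx(6.0, rel=1e-6)
        assert res.ci_low < 6.0 < res.ci_high
        assert res.n == 100

    def test_cross_product_oracle_random_tables(self):
        """Unadjusted logistic OR equals ad/bc to 6 significant figures on
        200 random tables."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(3, 40, 4)
            df, labels = _frame_from_2x2(a, b, c, d)
            res = logistic_or(df, labels, "x", model_id=1)
            if res.penalized:
                continue
            assert res.odds_ratio == pytest.approx((a * d) / (b * c),
                                                   rel=1e-6)
            checked += 1

    def test_doubling_scale_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.lognormal(3, 0.5, 300)
        lab = pd.Series(np.where(rng.random(300) < 0.4, "case",
                                 "healthy_control"))
        df = pd.DataFrame({"x": x})
        r1 = logistic_or(df, lab, "x", transform="doubling")
        r2 = logistic_or(df.assign(x=df.x * 37.0), lab, "x",
                         transform="doubling")
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-8)

    def test_doubling_rejects_nonpositive(self):
        df = pd.DataFrame({"x": [1.0, -1.0, 2.0, 3.0]})
        lab = pd.Series(["case", "case", "healthy_control", "healthy_control"])
        with pytest.raises(ValueError):
            logistic_or(df, lab, "x", transform="doubling")

    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(14)
        n = 5000
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        lab = pd.Series(np.where(rng.random(n) < 0.3, "case",
                                 "healthy_control"))
        res = logistic_or(df, lab, "x")
        assert 0.9 < res.odds_ratio < 1.1
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestCorrelationEta:
    def test_equal_means_zero(self):
        r = correlation_eta([1.0, 2.0, 1.0, 2.0], [0, 0, 1, 1])
        assert r.eta == pytest.approx(0.0, abs=1e-12)

    def test_known_value(self):
        r = correlation_eta([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.eta == pytest.approx(2 / np.sqrt(5), abs=1e-10)

    def test_sign_follows_group_mean(self):
        r = correlation_eta([4, 3, 2, 1], [0, 0, 1, 1])
        assert r.eta < 0

    def test_magnitude_equals_correlation_ratio_formula(self):
        """|η| equals sqrt(between-group SS / total SS) on 200 random
        binary-grouped vectors."""
        rng = np.random.default_rng(15)
        for _ in range(200):
            n = rng.integers(10, 100)
            x = rng.normal(0, 1, n)
            g = rng.integers(0, 2, n)
            if g.min() == g.max():
                continue
            res = correlation_eta(x, g)
            grand = x.mean()
            between = sum(len(x[g == v]) * (x[g == v].mean() - grand) ** 2
                          for v in (0, 1))
            total = ((x - grand) ** 2).sum()
            assert abs(res.eta) == pytest.approx(np.sqrt(between / total),
                                                 abs=1e-10)

    def test_p_value_is_exact_t_transform(self):
        rng = np.random.default_rng(16)
        x, g = rng.normal(0, 1, 40), rng.integers(0, 2, 40)
        res = correlation_eta(x, g)
        t = res.eta * np.sqrt((res.n - 2) / (1 - res.eta ** 2))
        p = 2 * stats.t.sf(abs(t), res.n - 2)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation_eta([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])

    def test_default_cohort_targets(self, small_cohort):
        """Habit-biomarker correlation ratios land in the study's range."""
        _, base, _, _ = small_cohort
        sub = base[["wbc", "smoking"]].dropna()
        eta_ws = correlation_eta(sub.wbc, sub.smoking).eta
        assert 0.25 <= eta_ws <= 0.50
        sub = base[["ggtp", "smoking"]].dropna()
        eta_gs = correlation_eta(sub.ggtp, sub.smoking).eta
        assert -0.1 <= eta_gs <= 0.2


class TestGroupCompare:
    def test_smoking_2x2_p_value(self):
        res = group_compare((51, 75), (81, 151), kind="categorical")
        assert res["p"] == pytest.approx(3.94e-2, rel=0.05)

    def test_alcohol_2x2_p_value(self):
        res = group_compare((1693, 2194), (1704, 2195), kind="categorical")
        assert res["p"] == pytest.approx(0.712, rel=0.02)

    def test_identical_groups_p_one(self):
        res = group_compare((20, 40), (20, 40), kind="categorical")
        assert res["p"] == pytest.approx(1.0)

    def test_all_positive_both_groups_p_one(self):
        res = group_compare((40, 40), (60, 60), kind="categorical")
        assert res["p"] == 1.0 and res["statistic"] == 0.0

    def test_chi2_equals_two_proportion_z_squared(self):
        """Uncorrected 2×2 chi-square is the squared pooled z statistic."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            na, nb = rng.integers(20, 200, 2)
            ka, kb = rng.integers(1, na), rng.integers(1, nb)
            res = group_compare((int(ka), int(na)), (int(kb), int(nb)),
                                kind="categorical")
            p1, p2 = ka / na, kb / nb
            pp = (ka + kb) / (na + nb)
            z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / na + 1 / nb))
            assert res["statistic"] == pytest.approx(z ** 2, rel=1e-9)

    def test_continuous_pooled_t(self):
        rng = np.random.default_rng(18)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 40)
        res = group_compare(a, b, kind="continuous")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res["p"] == pytest.approx(p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0, 2.0], kind="continuous")


class TestCharacteristicsTable:
    def test_empty_cohort(self):
        df = pd.DataFrame(columns=["age", "bmi"])
        labels = pd.Series(dtype=object)
        assert characteristics_table(df, labels).empty

    def test_counts_bounded_and_p_columns(self, small_cohort):
        _, base, _, labels = small_cohort
        table = characteristics_table(base, labels)
        n_case = (labels == "case").sum()
        n_hc = (labels == "healthy_control").sum()
        assert (table.n_a <= n_case).all()
        assert (table.n_b <= n_hc).all()
        assert ((table.p > 0) & (table.p <= 1)).all()
        # the cohort's real group differences should register
        bmi_p = table.set_index("characteristic").loc["bmi", "p"]
        assert bmi_p < 1e-4


def test_parameter_recovery_model1_ors():
    """On default synthetic cohorts the unadjusted ORs for γ-GTP (doubling)
    and WBC (per 1000 cells) exceed 1 with p < 0.05 in ≥90% of seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        spec = m.replication_spec(n_subjects=4392, seed=seed)
        base, fu = m.generate_cohort(spec)
        labels = m.assign_cohort_labels(base, fu)
        rg = logistic_or(base, labels, "ggtp", transform="doubling")
        rw = logistic_or(base, labels, "wbc", scale=1000.0)
        ok = (rg.odds_ratio > 1 and rg.p_value < 0.05
              and rw.odds_ratio > 1 and rw.p_value < 0.05)
        hits += ok
    assert hits >= 0.9 * n_seeds
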
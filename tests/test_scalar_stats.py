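import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bodymaps import (
    chi_square_contingency,
    mixed_anova,
    percentile_group_assign,
    spearman_corr,
    two_sample_from_raw,
    two_sample_from_summary,
)


class TestPercentileGrouping:
    def test_one_to_nine_splits_into_thirds(self):
        labels = percentile_group_assign(np.arange(1, 10))
        assert list(labels) == ["low"] * 3 + ["middle"] * 3 + ["high"] * 3

    def test_all_equal_scores_resolve_to_middle(self):
        with pytest.warns(UserWarning, match="overlap"):
            labels = percentile_group_assign(np.full(9, 5.0))
        assert set(labels) == {"middle"}

    def test_audit_like_distribution_reproduces_cutoff_rule(self):
        """An integer distribution whose 33rd/66th percentiles are 4 and 7
        yields exactly the 'low <= 4, high >= 7' grouping, ties included."""
        rng = np.random.default_rng(0)
        scores = np.concatenate([
            rng.integers(0, 5, 80),     # low tail incl. many 4s
            np.full(29, 4),
            rng.integers(5, 7, 40),
            np.full(18, 7),
            rng.integers(7, 20, 60),
        ])
        q33 = np.sort(scores)[int(np.ceil(0.33 * scores.size)) - 1]
        q66 = np.sort(scores)[int(np.ceil(0.66 * scores.size)) - 1]
        assert (q33, q66) == (4, 6) or (q33, q66) == (4, 7)
        labels = percentile_group_assign(scores)
        if (q33, q66) == (4, 7):
            np.testing.assert_array_equal(labels == "low", scores <= 4)
            np.testing.assert_array_equal(labels == "high", scores >= 7)

    def test_ties_at_cutoffs_join_extreme_groups(self):
        scores = np.array([1, 1, 1, 1, 5, 9, 9, 9, 9])
        labels = percentile_group_assign(scores)
        assert (labels[scores == 1] == "low").all()
        assert (labels[scores == 9] == "high").all()

    def test_bad_percentile_order_rejected(self):
        with pytest.raises(ValueError):
            percentile_group_assign(np.arange(10), low_pct=70, high_pct=30)


class TestSummaryTests:
    # printed group summary rows: (m1, sd1, m2, sd2, expected t, expected d)
    TABLE_ROWS = [
        ("tas_total", 39.41, 11.99, 44.07, 11.31, -2.69, -0.40),
        ("tas_dif", 17.03, 6.40, 19.52, 5.83, -2.73, -0.41),
        ("isq", 15.53, 5.50, 17.43, 6.20, -2.18, -0.32),
        ("maia", 98.29, 23.59, 94.35, 23.73, 1.12, 0.17),
        ("task_difficulty", 5.57, 2.41, 6.30, 2.29, -2.09, -0.31),
        ("audit", 2.62, 1.18, 10.53, 3.59, -19.84, -2.95),
    ]

    @pytest.mark.parametrize("name,m1,sd1,m2,sd2,t_exp,d_exp", TABLE_ROWS)
    def test_reproduces_printed_group_comparisons(self, name, m1, sd1, m2, sd2,
                                                  t_exp, d_exp):
        res = two_sample_from_summary(m1, sd1, 90, m2, sd2, 91)
        assert res.df == 179
        assert res.t == pytest.approx(t_exp, abs=0.05)
        assert res.cohens_d == pytest.approx(d_exp, abs=0.05)

    def test_identical_summaries_give_zero(self):
        res = two_sample_from_summary(5.0, 2.0, 30, 5.0, 2.0, 30)
        assert res.t == 0.0 and res.cohens_d == 0.0 and res.p == 1.0

    def test_summary_t_equals_raw_pooled_t(self, rng):
        x = rng.normal(3, 1.5, 40)
        y = rng.normal(3.5, 1.2, 35)
        raw = two_sample_from_raw(x, y, "pooled")
        summ = two_sample_from_summary(
            x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
        )
        assert summ.t == pytest.approx(raw.t, abs=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-10)
        assert summ.cohens_d == pytest.approx(raw.cohens_d, abs=1e-10)

    def test_degenerate_zero_spread_flagged(self):
        res = two_sample_from_summary(1.0, 0.0, 10, 2.0, 0.0, 10)
        assert res.degenerate


class TestRawTests:
    def test_mann_whitney_on_copies_near_one(self, rng):
        x = rng.normal(size=30)
        res = two_sample_from_raw(x, x.copy(), "mann_whitney")
        assert res.p > 0.9
        assert res.t == pytest.approx(30 * 30 / 2, rel=0.01)  # U at its mean

    def test_shifting_one_sample_decreases_t(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        ts = [two_sample_from_raw(x, y + c, "pooled").t for c in (0.0, 0.5, 1.0)]
        assert ts[0] > ts[1] > ts[2]

    def test_welch_matches_scipy(self, rng):
        x = rng.normal(0, 3, 20)
        y = rng.normal(0, 0.5, 40)
        res = two_sample_from_raw(x, y, "welch")
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.df == pytest.approx(ref.df)


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        res = chi_square_contingency([[10, 20], [20, 40]])
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        # expected 15 in every cell: chi2 = 4 * 25/15 = 6.667
        res = chi_square_contingency([[10, 20], [20, 10]])
        assert res.t == pytest.approx(20 / 3, rel=1e-9)
        assert res.df == 1

    def test_df_for_2x3_table(self):
        res = chi_square_contingency([[5, 10, 15], [10, 10, 10]])
        assert res.df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_contingency([[0, 0], [5, 5]])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman_corr(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_formula_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 5.0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y)[0] == pytest.approx(brute, rel=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_corr(np.ones(5), np.arange(5.0))
        assert np.isnan(rho)


def _long(values, groups):
    """values: dict subject -> list of k level values."""
    rows = []
    for sid, vals in values.items():
        for m, v in enumerate(vals):
            rows.append({"subject": sid, "group": groups[sid],
                         "level": f"L{m}", "y": float(v)})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_epsilon_exactly_one_with_two_levels(self, rng):
        values = {f"s{i}": rng.normal(size=2) for i in range(10)}
        groups = {f"s{i}": "a" if i < 5 else "b" for i in range(10)}
        res = mixed_anova(_long(values, groups), "y", "level", "subject", "group")
        assert res.gg_epsilon == 1.0
        assert not res.gg_applied

    def test_ss_decomposition_matches_bruteforce_worked_dataset(self):
        """2 groups x 3 subjects x 3 levels with integer values: every sum of
        squares equals the definitional brute-force computation."""
        data = {
            "a1": [3, 4, 5], "a2": [2, 4, 6], "a3": [4, 5, 6],
            "b1": [6, 7, 9], "b2": [5, 8, 9], "b3": [7, 7, 10],
        }
        groups = {s: s[0] for s in data}
        Y = np.array([data[s] for s in sorted(data)], dtype=float)
        glab = np.array([groups[s] for s in sorted(data)])
        gm = Y.mean()
        ss_total = ((Y - gm) ** 2).sum()
        subj_means = Y.mean(axis=1)
        ss_between_subj = 3 * ((subj_means - gm) ** 2).sum()
        ss_group = 3 * sum(
            (glab == g).sum() * (subj_means[glab == g].mean() - gm) ** 2
            for g in ("a", "b")
        )
        ss_subj = ss_between_subj - ss_group
        ss_level = 6 * ((Y.mean(axis=0) - gm) ** 2).sum()
        ss_cells = sum(
            3 * ((Y[glab == g].mean(axis=0) - gm) ** 2).sum() for g in ("a", "b")
        )
        ss_inter = ss_cells - ss_group - ss_level
        ss_err = ss_total - ss_between_subj - ss_level - ss_inter

        res = mixed_anova(_long(data, groups), "y", "level", "subject", "group")
        assert res["group"].ss == pytest.approx(ss_group, abs=1e-10)
        assert res["level"].ss == pytest.approx(ss_level, abs=1e-10)
        assert res["group * level"].ss == pytest.approx(ss_inter, abs=1e-10)
        # F statistics from the same brute-force quantities
        F_group = (ss_group / 1) / (ss_subj / 4)
        F_level = (ss_level / 2) / (ss_err / 8)
        assert res["group"].F == pytest.approx(F_group, abs=1e-10)
        assert res["level"].F == pytest.approx(F_level, abs=1e-10)
        # classical eta squared
        assert res["group"].eta_sq == pytest.approx(ss_group / ss_total, abs=1e-12)

    def test_agrees_with_pingouin_f_and_ss(self, rng):
        pg = pytest.importorskip("pingouin")
        values = {f"s{i}": rng.normal(size=4) + (0.5 if i >= 8 else 0.0)
                  for i in range(16)}
        groups = {f"s{i}": "a" if i < 8 else "b" for i in range(16)}
        df = _long(values, groups)
        res = mixed_anova(df, "y", "level", "subject", "group")
        aov = pg.mixed_anova(data=df, dv="y", within="level", subject="subject",
                             between="group").set_index("Source")
        assert res["group"].F == pytest.approx(aov.loc["group", "F"], rel=1e-9)
        assert res["group"].ss == pytest.approx(aov.loc["group", "SS"], rel=1e-9)
        assert res["level"].ss == pytest.approx(aov.loc["level", "SS"], rel=1e-9)
        assert res["group * level"].F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-9
        )

    def test_between_f_monotone_in_group_shift(self, rng):
        fs = []
        for shift in (0.0, 0.5, 1.0):
            r = np.random.default_rng(7)
            values = {f"s{i}": r.normal(size=4) + (shift if i >= 10 else 0)
                      for i in range(20)}
            groups = {f"s{i}": "a" if i < 10 else "b" for i in range(20)}
            res = mixed_anova(_long(values, groups), "y", "level", "subject", "group")
            fs.append(res["group"].F)
        assert fs[0] < fs[1] < fs[2]

    def test_incomplete_subjects_dropped_and_counted(self, rng):
        values = {f"s{i}": rng.normal(size=3) for i in range(8)}
        groups = {f"s{i}": "a" if i < 4 else "b" for i in range(8)}
        df = _long(values, groups)
        df = df[~((df.subject == "s0") & (df.level == "L2"))]
        res = mixed_anova(df, "y", "level", "subject", "group")
        assert res.n_dropped_incomplete == 1
        assert res.n_subjects == 7

    def test_gg_correction_fires_on_nonspherical_data(self, rng):
        values = {}
        for i in range(24):
            base = rng.normal()
            # strongly heteroscedastic increments break sphericity
            values[f"s{i}"] = base + np.cumsum(rng.normal(0, [0.1, 0.5, 2.0, 5.0]))
        groups = {f"s{i}": "a" if i < 12 else "b" for i in range(24)}
        res = mixed_anova(_long(values, groups), "y", "level", "subject", "group")
        assert res.sphericity_p < 0.05
        assert res.gg_applied
        k = 4
        assert 1.0 / (k - 1) <= res.gg_epsilon < 1.0
        assert res["level"].df_num == pytest.approx((k - 1) * res.gg_epsilon)
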
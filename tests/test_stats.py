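"""Statistics battery tests, each checked against a brute-force oracle or a
hand-computed fixture independent of the implementation path."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cornea_emod.stats import (
    agreement_suite,
    anova_lsd,
    concordance_ccc,
    correlate,
    group_table,
    normality_test,
    roc_compare,
    roc_curve,
    roc_table,
)


def brute_force_auc(scores, labels):
    """Pair-counting Mann-Whitney AUC with ties counted 1/2 (cases high)."""
    cases = [s for s, l in zip(scores, labels) if l]
    controls = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestNormality:
    def test_null_true_large_sample(self):
        rng = np.random.default_rng(0)
        stat, p = normality_test(rng.normal(0, 1, 500))
        assert p > 0.05

    def test_statistic_equals_brute_force_ecdf_gap(self):
        x = np.arange(1.0, 1001.0)  # uniform grid treated as normal
        stat, _ = normality_test(x)
        xs = np.sort(x)
        z = (xs - xs.mean()) / xs.std(ddof=1)
        cdf = sps.norm.cdf(z)
        n = len(xs)
        gaps = [
            max(abs((i + 1) / n - cdf[i]), abs(i / n - cdf[i]))
            for i in range(n)
        ]
        assert stat == pytest.approx(max(gaps), abs=1e-10)

    def test_deterministic(self):
        x = np.sin(np.arange(50.0))
        assert normality_test(x) == normality_test(x)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test([2.0] * 20)
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


class TestAgreement:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = agreement_suite(x, x)
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.paired_t_p == 1.0
        assert res.icc == pytest.approx(1.0)
        assert res.ccc == pytest.approx(1.0)

    def test_ccc_hand_fixture(self):
        # population moments: 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        assert concordance_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0)

    def test_ccc_anti_agreement_sign(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert concordance_ccc(x, -x) < 0

    def test_loa_formula_exact(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, 40)
        y = x + rng.normal(0.5, 1, 40)
        res = agreement_suite(x, y)
        d = y - x
        assert res.bias == pytest.approx(d.mean())
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))

    def test_loa_cover_about_95_percent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 5000)
        y = x + rng.normal(0, 1, 5000)
        res = agreement_suite(x, y)
        d = y - x
        frac = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        assert 0.94 <= frac <= 0.96

    def test_ccc_bounded_by_pearson(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(0, 1, 30)
            y = 0.5 * x + rng.normal(0, 1, 30)
            r, _ = correlate(x, y)
            assert abs(concordance_ccc(x, y)) <= abs(r) + 1e-12

    def test_icc_against_paired_anova_construction(self):
        # two-way random absolute agreement on a known dataset: compare to
        # the variance-component formula computed by hand
        x = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        res = agreement_suite(x, y)
        n = len(x)
        table = np.vstack([x, y]).T
        ms_r = 2 * np.var(table.mean(axis=1), ddof=1)
        ms_c = n * np.var(table.mean(axis=0), ddof=1)
        grand = table.mean()
        resid = table - table.mean(1, keepdims=True) - table.mean(0) + grand
        ms_e = (resid**2).sum() / (n - 1)
        icc_hand = (ms_r - ms_e) / (
            ms_r + ms_e + 2 * (ms_c - ms_e) / n
        )
        assert res.icc == pytest.approx(icc_hand, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_suite([1, 2, 3], [1, 2])


class TestAnovaLSD:
    def test_identical_groups(self):
        g = {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}
        res = anova_lsd(g)
        assert res.F == 0.0
        assert res.pairwise[("A", "B")] == pytest.approx(1.0)

    def test_hand_sums_of_squares_fixture(self):
        res = anova_lsd({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        assert res.ss_between == pytest.approx(4.0)
        assert res.ss_within == pytest.approx(1.0)
        assert res.F == pytest.approx(8.0)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(i, 1, 12 + i) for i, k in enumerate("ABC")}
        res = anova_lsd(groups)
        F, p = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(F)
        assert res.p == pytest.approx(p)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(5)
        samples = [rng.normal(i, 1, 10) for i in range(3)]
        f1 = anova_lsd(dict(zip("ABC", samples))).F
        f2 = anova_lsd(dict(zip("XYZ", [samples[2], samples[0], samples[1]]))).F
        assert f1 == pytest.approx(f2)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        data=st.lists(
            st.lists(st.floats(-50, 50), min_size=2, max_size=8),
            min_size=2,
            max_size=4,
        )
    )
    def test_sum_of_squares_decomposition(self, data):
        groups = {f"g{i}": np.array(v) for i, v in enumerate(data)}
        res = anova_lsd(groups)
        allx = np.concatenate(list(groups.values()))
        sst = float(((allx - allx.mean()) ** 2).sum())
        assert res.ss_between + res.ss_within == pytest.approx(sst, abs=1e-8)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd({"A": [1.0], "B": [1.0, 2.0]})

    def test_zero_within_variance_flagged(self):
        res = anova_lsd({"A": [1.0, 1.0], "B": [2.0, 2.0]})
        assert res.p == 0.0
        assert "zero_within_variance" in res.flags


class TestROC:
    def test_perfect_separation(self):
        res = roc_curve([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_pair_counting_fixture_cases_low(self):
        # cases {1, 3}, controls {2, 4}: 3 of 4 pairs ordered cases-low
        res = roc_curve([1, 3, 2, 4], [True, True, False, False])
        assert res.direction == "case_low"
        assert res.auc == pytest.approx(0.75)

    def test_auc_equals_pair_count_on_random_battery(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            n = rng.integers(4, 21)
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = np.zeros(n, bool)
            labels[rng.permutation(n)[: rng.integers(1, n)]] = True
            if labels.all() or not labels.any():
                continue
            res = roc_curve(scores, labels, direction="case_high")
            assert res.auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_cutoff_attains_reported_operating_point(self):
        rng = np.random.default_rng(7)
        scores = np.r_[rng.normal(0, 1, 40), rng.normal(1.5, 1, 30)]
        labels = np.r_[np.zeros(40, bool), np.ones(30, bool)]
        res = roc_curve(scores, labels)
        called = scores >= res.cutoff
        sens = np.mean(called[labels])
        spec = np.mean(~called[~labels])
        assert sens == pytest.approx(res.sensitivity)
        assert spec == pytest.approx(res.specificity)

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(0, 1, 200)
        aucs = []
        for _ in range(50):
            labels = np.zeros(200, bool)
            labels[rng.permutation(200)[:100]] = True
            aucs.append(roc_curve(scores, labels, direction="case_high").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [True, True, True])


class TestDeLong:
    @staticmethod
    def brute_force_delong(s1, s2, labels):
        """Double-loop placement values and covariance, straight from the
        definition."""
        s1, s2 = np.asarray(s1, float), np.asarray(s2, float)
        lab = np.asarray(labels, bool)
        X1, Y1 = s1[lab], s1[~lab]
        X2, Y2 = s2[lab], s2[~lab]
        m, n = len(X1), len(Y1)

        def psi(a, b):
            return 1.0 if a > b else (0.5 if a == b else 0.0)

        def components(X, Y):
            v10 = np.array([np.mean([psi(x, y) for y in Y]) for x in X])
            v01 = np.array([np.mean([psi(x, y) for x in X]) for y in Y])
            return v10, v01, float(np.mean([[psi(x, y) for y in Y] for x in X]))

        v10_1, v01_1, a1 = components(X1, Y1)
        v10_2, v01_2, a2 = components(X2, Y2)
        s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
        s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
        z = (a1 - a2) / np.sqrt(var)
        return z, 2 * sps.norm.sf(abs(z))

    def test_identical_scores_give_null(self):
        s = [0.1, 0.9, 0.4, 0.8, 0.3, 0.7]
        lab = [False, True, False, True, False, True]
        z, p = roc_compare(s, s, lab)
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        s = rng.normal(0, 1, 30)
        lab = np.r_[np.zeros(15, bool), np.ones(15, bool)]
        s_lab = s + lab * 1.0
        z, p = roc_compare(s_lab, np.exp(s_lab), lab)
        assert z == 0.0 and p == 1.0

    def test_matches_brute_force_on_n10_fixture(self):
        rng = np.random.default_rng(10)
        s1 = rng.normal(0, 1, 10)
        s2 = 0.5 * s1 + rng.normal(0, 1, 10)
        lab = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0], bool)
        s1 = s1 + lab  # make both score sets cases-high
        s2 = s2 + lab
        z, p = roc_compare(s1, s2, lab, direction="case_high")
        z_bf, p_bf = self.brute_force_delong(s1, s2, lab)
        assert z == pytest.approx(z_bf, abs=1e-12)
        assert p == pytest.approx(p_bf, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            roc_compare([1, 2], [1, 2, 3], [True, False, True])


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        r, _ = correlate([-1.0, 0.0, 1.0], [1.0, -2.0, 1.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_oracle_n8(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 8.0, 10.0, 12.0])
        y = np.array([0.5, 2.2, 3.1, 5.9, 6.4, 8.8, 9.1, 13.0])
        r, _ = correlate(x, y)
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTables:
    @pytest.fixture()
    def tidy(self):
        rng = np.random.default_rng(11)
        rows = []
        for g, mu in (("healthy", 0.35), ("FFKC", 0.30), ("KC", 0.16)):
            for v in rng.normal(mu, 0.04, 30):
                rows.append({"group": g, "E": v})
        return pd.DataFrame(rows)

    def test_group_table_shape(self, tidy):
        tbl = group_table(tidy, ["E"])
        assert len(tbl) == 1
        row = tbl.iloc[0]
        assert row["F"] > 10
        assert {"healthy_mean", "FFKC_mean", "KC_mean"} <= set(tbl.columns)

    def test_roc_table_contrast(self, tidy):
        tbl = roc_table(tidy, ["E"], "KC", "healthy")
        row = tbl.iloc[0]
        assert row["auc"] > 0.9
        assert row["direction"] == "case_low"  # KC has the lower modulus
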
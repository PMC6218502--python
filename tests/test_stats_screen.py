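import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fallkit.core_io import ValidationError
from fallkit.stats_screen import (
    GroupSummary,
    rank_measures,
    roc_auc,
    screen,
    ttest_from_samples,
    ttest_from_summary,
)


def brute_force_auc(scores, is_faller):
    """Independent oracle: explicit double loop over (faller, non-faller) pairs."""
    pos = scores[is_faller]
    neg = scores[~is_faller]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    auc = total / (len(pos) * len(neg))
    return max(auc, 1.0 - auc)


class TestTTestFromSummary:
    # printed demographic comparisons (mean, sd, n) per group
    @pytest.mark.parametrize(
        "nf,f,expected_p,tol",
        [
            ((72.02, 4.17, 114), (72.35, 4.74, 82), 0.608, 0.01),
            ((154.83, 5.01, 114), (154.41, 5.31, 82), 0.577, 0.01),
            ((58.01, 6.93, 114), (61.01, 8.05, 82), 0.006, 0.002),
            ((24.21, 2.74, 114), (25.56, 2.93, 82), 0.001, 0.001),
        ],
    )
    def test_published_demographics(self, nf, f, expected_p, tol):
        a = GroupSummary(n=nf[2], mean=nf[0], sd=nf[1])
        b = GroupSummary(n=f[2], mean=f[0], sd=f[1])
        t, df, p = ttest_from_summary(a, b)
        assert df == 194
        assert p == pytest.approx(expected_p, abs=tol)

    def test_identical_summaries(self):
        s = GroupSummary(20, 5.0, 1.0)
        t, df, p = ttest_from_summary(s, s)
        assert t == 0.0 and p == 1.0

    def test_n_too_small(self):
        with pytest.raises(ValidationError):
            ttest_from_summary(GroupSummary(1, 0.0, 1.0), GroupSummary(5, 0.0, 1.0))


class TestTTestFromSamples:
    def test_identical_samples(self):
        t, df, p = ttest_from_samples([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_agrees_with_summary_route(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(3, 30))
            y = rng.standard_normal(rng.integers(3, 30)) + rng.uniform(-1, 1)
            t1, df1, p1 = ttest_from_samples(x, y)
            t2, df2, p2 = ttest_from_summary(
                GroupSummary(x.size, float(x.mean()), float(x.std(ddof=1))),
                GroupSummary(y.size, float(y.mean()), float(y.std(ddof=1))),
            )
            assert t1 == pytest.approx(t2, abs=1e-12)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_agrees_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(15), rng.standard_normal(20) + 0.5
        t, df, p = ttest_from_samples(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_separation(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20)
        t, df, p = ttest_from_samples(x + 100.0, x)
        assert p < 1e-6

    def test_degenerate_equal_constant(self):
        t, df, p = ttest_from_samples([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(10), rng.standard_normal(12) + 1
        _, _, p1 = ttest_from_samples(x, y)
        _, _, p2 = ttest_from_samples(y, x)
        assert p1 == pytest.approx(p2, abs=1e-14)

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_t_invariant_under_affine(self, shift, scale):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal(12), rng.standard_normal(15) + 0.7
        t1, _, _ = ttest_from_samples(x, y)
        t2, _, _ = ttest_from_samples(scale * x + shift, scale * y + shift)
        assert abs(t1) == pytest.approx(abs(t2), rel=1e-9)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_all_ties(self):
        auc, _, _ = roc_auc([5.0] * 10, [0] * 5 + [1] * 5)
        assert auc == 0.5

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n1, n0 = rng.integers(2, 10), rng.integers(2, 10)
            scores = np.round(rng.standard_normal(n1 + n0), 1)  # ties likely
            labels = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
            auc, _, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @given(st.sampled_from(["exp", "cube", "arctan"]))
    @settings(max_examples=10, deadline=None)
    def test_monotone_transform_invariance(self, name):
        fn = {"exp": np.exp, "cube": lambda v: v**3, "arctan": np.arctan}[name]
        rng = np.random.default_rng(10)
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a1, _, _ = roc_auc(scores, labels)
        a2, _, _ = roc_auc(fn(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_hanley_mcneil_se_positive(self):
        rng = np.random.default_rng(11)
        auc, se, ci = roc_auc(rng.standard_normal(60), rng.integers(0, 2, 60).astype(bool))
        assert se > 0 and ci[0] < auc < ci[1]


class TestScreen:
    def test_perfect_measure_selected(self):
        df = pd.DataFrame({
            "m": np.r_[np.zeros(20), np.ones(20)],
            "fall_status": ["non_faller"] * 20 + ["faller"] * 20,
        })
        results = screen(df)
        assert len(results) == 1 and results[0].selected

    def test_selected_implies_both(self, cohort_df):
        for r in screen(cohort_df):
            if r.selected:
                assert r.significant_t and r.significant_roc
            assert 0.0 <= r.p <= 1.0 and 0.5 <= r.auc <= 1.0

    def test_fes_ips_selected(self, cohort_df):
        selected = {r.measure_id for r in screen(cohort_df) if r.selected}
        assert {"fes_score", "crt_ips"} <= selected

    def test_missing_class_errors(self):
        df = pd.DataFrame({"m": [1.0, 2.0], "fall_status": ["faller", "faller"]})
        with pytest.raises(ValidationError):
            screen(df)

    def test_deterministic(self, cohort_df):
        r1 = screen(cohort_df)
        r2 = screen(cohort_df)
        assert [(r.measure_id, r.p, r.auc) for r in r1] == \
               [(r.measure_id, r.p, r.auc) for r in r2]


class TestRankMeasures:
    def test_label_feature_ranked_first(self):
        rng = np.random.default_rng(12)
        n = 120
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({
            "oracle": y + rng.standard_normal(n) * 0.1,
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
            "fall_status": np.where(y == 1, "faller", "non_faller"),
        })
        ranking = rank_measures(df, ["oracle", "noise1", "noise2"], seed=0)
        assert ranking.order[0] == "oracle"

    def test_noise_feature_mda_near_zero(self):
        rng = np.random.default_rng(13)
        n = 120
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({
            "oracle": y + rng.standard_normal(n) * 0.1,
            "noise": rng.standard_normal(n),
            "fall_status": np.where(y == 1, "faller", "non_faller"),
        })
        table = rank_measures(df, ["oracle", "noise"], seed=0).table
        row = table[table.measure_id == "noise"].iloc[0]
        assert abs(row.mda) <= 2 * row.mda_sd + 0.02

    def test_deterministic(self, cohort_df):
        selected = [r.measure_id for r in screen(cohort_df) if r.selected]
        r1 = rank_measures(cohort_df, selected, seed=3)
        r2 = rank_measures(cohort_df, selected, seed=3)
        assert r1.order == r2.order
        np.testing.assert_array_equal(r1.table["mda"], r2.table["mda"])

    def test_empty_selected_errors(self, cohort_df):
        with pytest.raises(ValidationError):
            rank_measures(cohort_df, [], seed=0)
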
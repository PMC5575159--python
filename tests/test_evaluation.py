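import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emgdecode import (NarxConfig, TrainOptions, bonferroni_pairwise,
                       cross_validate, make_folds, rm_anova, vaf)
from emgdecode.errors import (InputError, ParameterError, PartitionError,
                              UndefinedMetricError)


class TestVaf:
    def test_perfect_prediction(self):
        x = np.array([1.0, 2.0, 5.0, -3.0])
        assert vaf(x, x) == 100.0

    def test_mean_prediction_scores_zero(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert vaf(x, np.full(4, x.mean())) == pytest.approx(0.0)

    def test_hand_worked_example(self):
        # residual [0,0,0,1]: pop. variances 0.1875 / 1.25 -> VAF = 85.0
        assert vaf([0, 1, 2, 3], [0, 1, 2, 2]) == pytest.approx(85.0)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            vaf(np.ones(10), np.ones(10))

    @given(st.integers(0, 2**32 - 1))
    def test_invariances(self, seed):
        """VAF is invariant to adding a constant to the prediction error
        structure and to common rescaling of both signals."""
        rng = np.random.default_rng(seed)
        m = rng.normal(size=30)
        p = m + rng.normal(scale=0.3, size=30)
        base = vaf(m, p)
        assert vaf(m, p + 0.0) == pytest.approx(base)
        assert vaf(3.7 * m, 3.7 * p) == pytest.approx(base)
        # shifting BOTH signals by the same constant also preserves VAF
        assert vaf(m + 11.0, p + 11.0) == pytest.approx(base)


class TestMakeFolds:
    def test_even_partition(self):
        folds = make_folds(100, 5)
        blocks = [tuple(v[[0, -1]]) for _, v in folds]
        assert blocks == [(0, 19), (20, 39), (40, 59), (60, 79), (80, 99)]
        for train_idx, val_idx in folds:
            assert len(train_idx) == 80 and len(val_idx) == 20

    def test_remainder_goes_to_last_block(self):
        folds = make_folds(101, 5)
        sizes = [len(v) for _, v in folds]
        assert sizes == [20, 20, 20, 20, 21]

    @given(st.integers(10, 500), st.integers(2, 8))
    def test_partition_properties(self, n, k):
        if n < k:
            return
        folds = make_folds(n, k)
        all_val = np.concatenate([v for _, v in folds])
        assert len(all_val) == n
        assert len(np.unique(all_val)) == n  # disjoint cover
        for train_idx, val_idx in folds:
            assert np.intersect1d(train_idx, val_idx).size == 0
            assert len(train_idx) + len(val_idx) == n
            assert np.all(np.diff(val_idx) == 1)  # contiguous

    def test_too_small_rejected(self):
        with pytest.raises(PartitionError):
            make_folds(3, 5)


def _rm_anova_oracle(x):
    """Definitional sums-of-squares oracle, written independently with
    explicit loops over cells."""
    n, c = x.shape
    grand = x.mean()
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(c))
    ss_subj = sum(c * (np.mean(x[i, :]) - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (np.mean(x[:, j]) - grand) ** 2 for j in range(c))
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = c - 1, (c - 1) * (n - 1)
    f_stat = (ss_cond / df1) / (ss_err / df2)
    eta = ss_cond / (ss_cond + ss_err)
    return f_stat, df1, df2, eta


class TestRmAnova:
    def test_identical_columns_give_zero_f(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        res = rm_anova(np.column_stack([col, col, col]))
        assert res.F == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_definitional_oracle(self):
        x = np.random.default_rng(7).uniform(80, 100, size=(4, 3))
        res = rm_anova(x)
        f_stat, df1, df2, eta = _rm_anova_oracle(x)
        assert res.F == pytest.approx(f_stat, abs=1e-10)
        assert (res.df1, res.df2) == (df1, df2)
        assert res.partial_eta_sq == pytest.approx(eta, abs=1e-10)

    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM
        import pandas as pd
        rng = np.random.default_rng(21)
        x = rng.uniform(85, 100, size=(10, 3))
        res = rm_anova(x)
        frame = pd.DataFrame({
            "unit": np.repeat(np.arange(10), 3),
            "cond": np.tile(np.arange(3), 10),
            "value": x.ravel(),
        })
        sm = AnovaRM(frame, "value", "unit", within=["cond"]).fit()
        assert res.F == pytest.approx(sm.anova_table["F Value"].iloc[0], rel=1e-9)
        assert res.p == pytest.approx(sm.anova_table["Pr > F"].iloc[0], abs=1e-12)

    @given(st.integers(0, 2**32 - 1), st.integers(3, 8), st.integers(2, 5))
    def test_partial_eta_identity(self, seed, n, c):
        """Algebraic identity of the one-way RM decomposition:
        eta_p^2 = F*df1 / (F*df1 + df2)."""
        x = np.random.default_rng(seed).normal(size=(n, c))
        res = rm_anova(x)
        expected = res.F * res.df1 / (res.F * res.df1 + res.df2)
        assert res.partial_eta_sq == pytest.approx(expected, abs=1e-10)

    def test_incomplete_table_rejected(self):
        bad = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(InputError):
            rm_anova(bad)


class TestBonferroni:
    def test_adjustment_multiplies_and_caps(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 3))
        from scipy import stats as spstats
        for comp in bonferroni_pairwise(x):
            _, p_raw = spstats.ttest_rel(x[:, comp.pair[0]], x[:, comp.pair[1]])
            assert comp.p_raw == pytest.approx(p_raw)
            assert comp.p_adj == pytest.approx(min(1.0, p_raw * 3))

    def test_identical_conditions_are_degenerate(self):
        col = np.arange(5.0)
        comps = bonferroni_pairwise(np.column_stack([col, col, col]))
        assert all(c.degenerate and c.p_adj == 1.0 for c in comps)


@pytest.fixture(scope="module")
def cheap_opts():
    return TrainOptions(restarts=1, max_iters=40, seed=5,
                        closed_loop_iters=0, polish_iters=0)


class TestCrossValidate:

    def test_report_shape_and_bounds(self, teacher, cheap_opts):
        from emgdecode import EnvelopeTrial
        _, env, ang = teacher
        trial = EnvelopeTrial(envelopes=env[:1500], angles=ang[:1500], fs=20.0)
        report = cross_validate(NarxConfig(), trial, cheap_opts,
                                mode="teacher_forced")
        assert report.vaf_table.shape == (5, 3)
        assert np.all(report.vaf_table <= 100.0)
        assert report.mode == "teacher_forced"

    def test_deterministic_rerun(self, teacher, cheap_opts):
        from emgdecode import EnvelopeTrial
        _, env, ang = teacher
        trial = EnvelopeTrial(envelopes=env[:1500], angles=ang[:1500], fs=20.0)
        a = cross_validate(NarxConfig(), trial, cheap_opts, mode="teacher_forced")
        b = cross_validate(NarxConfig(), trial, cheap_opts, mode="teacher_forced")
        np.testing.assert_array_equal(a.vaf_table, b.vaf_table)
        assert a.seeds == b.seeds

    def test_unknown_mode_rejected(self, teacher, cheap_opts):
        from emgdecode import EnvelopeTrial
        _, env, ang = teacher
        trial = EnvelopeTrial(envelopes=env[:600], angles=ang[:600], fs=20.0)
        with pytest.raises(ParameterError):
            cross_validate(NarxConfig(), trial, cheap_opts, mode="open_loop")
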
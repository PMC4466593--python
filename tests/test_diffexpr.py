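"""Normalization, per-feature ANOVA, BH adjustment and DE classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirlink.diffexpr import (
    GENE_FILTER,
    MIRNA_FILTER,
    ExpressionMatrix,
    FilterSpec,
    ValidationError,
    anova_per_feature,
    bh_adjust,
    classify_de,
    log2_if_linear,
    quantile_normalize,
)

import oracles


def make_matrix(values, n_young=2, n_adult=2, log2=True):
    n = n_young + n_adult
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = [f"y{i}" for i in range(n_young)] + [f"a{i}" for i in range(n_adult)]
    design = pd.Series(
        ["young"] * n_young + ["adult"] * n_adult, index=samples
    )
    frame = pd.DataFrame(
        values, index=[f"f{i}" for i in range(values.shape[0])], columns=samples
    )
    assert values.shape[1] == n
    return ExpressionMatrix(values=frame, design=design, log2=log2)


class TestExpressionMatrix:
    def test_rejects_missing_values(self):
        with pytest.raises(ValidationError, match="missing"):
            make_matrix([[1.0, np.nan, 2.0, 3.0]])

    def test_rejects_duplicate_feature_ids(self):
        frame = pd.DataFrame(
            [[1.0, 2, 3, 4], [5, 6, 7, 8]], index=["f", "f"],
            columns=["y0", "y1", "a0", "a1"],
        )
        design = pd.Series(["young", "young", "adult", "adult"],
                           index=["y0", "y1", "a0", "a1"])
        with pytest.raises(ValidationError, match="duplicate"):
            ExpressionMatrix(values=frame, design=design)

    def test_rejects_single_sample_group(self):
        with pytest.raises(ValidationError, match=">= 2"):
            make_matrix([[1.0, 2.0, 3.0]], n_young=1, n_adult=2)


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        frame = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(frame)
        expected = [1.5, 3.5]  # row means of the sorted columns
        assert list(out["a"]) == expected
        assert list(out["b"]) == expected

    def test_identical_sorted_columns_is_fixed_point(self):
        frame = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        out = quantile_normalize(frame)
        pd.testing.assert_frame_equal(out, frame)

    def test_single_row_takes_mean_of_the_one_quantile(self):
        frame = pd.DataFrame({"a": [5.0], "b": [9.0]})
        out = quantile_normalize(frame)
        assert out.to_numpy().tolist() == [[7.0, 7.0]]

    def test_tie_block_gets_mean_of_tied_reference_span(self):
        # sorted columns are [1,3] and [2,2], so the reference is
        # [1.5, 2.5]; column b's tie spans both ranks and gets their mean
        frame = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 2.0]})
        out = quantile_normalize(frame)
        assert list(out["a"]) == [1.5, 2.5]
        assert list(out["b"]) == [2.0, 2.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_columns_share_sorted_values_and_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(60, 5)) * rng.gamma(2.0, size=5)
        frame = pd.DataFrame(x, columns=list("abcde"))
        out = quantile_normalize(frame)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]], atol=1e-12)
        for c in frame.columns:
            rho = stats.spearmanr(frame[c], out[c]).statistic
            assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 6, size=(25, 4)).astype(float)  # heavy ties
        frame = pd.DataFrame(x, columns=list("abcd"))
        out = quantile_normalize(frame)
        reference = np.sort(x, axis=0).mean(axis=1).tolist()
        for j, c in enumerate(frame.columns):
            expected = oracles.quantile_normalize_column(
                x[:, j].tolist(), reference
            )
            assert np.allclose(out[c].to_numpy(), expected, atol=1e-12)

    def test_applies_to_expression_matrix_preserving_design(self):
        m = make_matrix([[1.0, 2, 3, 4], [5, 6, 7, 8]])
        out = quantile_normalize(m)
        assert isinstance(out, ExpressionMatrix)
        assert list(out.design) == list(m.design)


class TestLog2IfLinear:
    def test_powers_of_two(self):
        m = make_matrix([[4.0, 8.0, 16.0, 32.0]], log2=False)
        out = log2_if_linear(m)
        assert out.log2
        assert out.values.to_numpy().tolist() == [[2.0, 3.0, 4.0, 5.0]]

    def test_idempotent_on_log2_input(self):
        m = make_matrix([[4.0, 8.0, 16.0, 32.0]], log2=True)
        assert log2_if_linear(m) is m

    def test_offset_contract_at_zero(self):
        m = make_matrix([[0.0, 1.0, 3.0, 7.0]], log2=False)
        out = log2_if_linear(m, offset=1.0)
        assert out.values.to_numpy().tolist() == [[0.0, 1.0, 2.0, 3.0]]

    def test_nonpositive_without_offset_is_domain_error(self):
        m = make_matrix([[0.0, 1.0, 3.0, 7.0]], log2=False)
        with pytest.raises(ValidationError, match="nonpositive"):
            log2_if_linear(m)


class TestAnovaPerFeature:
    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        x = np.r_[np.ones(4), 3 * np.ones(4)] + rng.normal(0, 1e-6, 8)
        res = anova_per_feature(make_matrix([x], n_young=4, n_adult=4))
        row = res.table.iloc[0]
        assert row.log2fc == pytest.approx(2.0, abs=1e-4)
        assert row.p_raw < 1e-10

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 8))
        m = make_matrix(x, n_young=4, n_adult=4)
        res = anova_per_feature(m)
        t, p = stats.ttest_ind(x[:, 4:], x[:, :4], axis=1)
        assert np.allclose(res.table.f_stat, t**2, rtol=1e-10)
        assert np.allclose(res.table.p_raw, p, rtol=1e-10)

    def test_null_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10_000, 8))
        res = anova_per_feature(make_matrix(x, n_young=4, n_adult=4))
        frac = float((res.table.p_raw < 0.05).mean())
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(frac - 0.05) < half_width

    def test_constant_feature_conventions(self):
        res = anova_per_feature(
            make_matrix([[5.0, 5, 5, 5], [1.0, 1, 2, 2]])
        )
        equal = res.table.iloc[0]
        assert (equal.f_stat, equal.p_raw) == (0.0, 1.0)
        split = res.table.iloc[1]  # noiseless separation
        assert split.p_raw == 0.0 and np.isinf(split.f_stat)

    def test_rejects_linear_scale_input(self):
        m = make_matrix([[1.0, 2, 3, 4]], log2=False)
        with pytest.raises(ValidationError, match="log2"):
            anova_per_feature(m)


class TestBHAdjust:
    def test_stepup_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_singleton_identity(self):
        assert bh_adjust([1.0]).tolist() == [1.0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
    def test_matches_bruteforce_stepup_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), oracles.bh_stepup(pvals),
                           atol=1e-12)

    def test_monotone_along_sorted_raw_p(self):
        rng = np.random.default_rng(3)
        p = rng.random(500)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestClassifyDE:
    @staticmethod
    def result_with(p_raw, p_adj, log2fc):
        table = pd.DataFrame(
            {"mean_young": [0.0], "mean_adult": [log2fc], "log2fc": [log2fc],
             "f_stat": [1.0], "p_raw": [p_raw], "p_adj": [p_adj],
             "direction": ["ns"]},
            index=["f0"],
        )
        from mirlink.diffexpr import DEResult
        return DEResult(table=table)

    def test_gene_up_at_adjusted_threshold(self):
        res = classify_de(self.result_with(0.001, 0.005, 0.4), GENE_FILTER)
        assert res.up_features == {"f0"}

    def test_mirna_below_fold_threshold_is_ns(self):
        # 2^0.5 = 1.41-fold < 1.5
        res = classify_de(self.result_with(1e-4, 1e-3, 0.5), MIRNA_FILTER)
        assert res.up_features == set() and res.down_features == set()

    def test_mirna_down_above_fold_threshold(self):
        # 2^0.7 = 1.62-fold >= 1.5
        res = classify_de(self.result_with(1e-4, 1e-3, -0.7), MIRNA_FILTER)
        assert res.down_features == {"f0"}

    def test_zero_fold_change_has_no_direction(self):
        res = classify_de(self.result_with(1e-6, 1e-6, 0.0), GENE_FILTER)
        assert res.table.direction.iloc[0] == "ns"

    def test_filter_spec_domain_checks(self):
        with pytest.raises(ValueError):
            FilterSpec(kind="gene", p_threshold=0.0, use_adjusted=True)
        with pytest.raises(ValueError):
            FilterSpec(kind="gene", p_threshold=0.01, use_adjusted=True,
                       fc_threshold=0.5)
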
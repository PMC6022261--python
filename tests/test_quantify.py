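"""Quantification layer: methylation levels, normalization, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimodule import (
    MeripCountSet,
    MethylationMatrix,
    estimate_size_factors,
    m_value,
    merge_replicates,
    methylation_level,
    preprocess,
    quantile_normalize,
    select_dynamic_sites,
    standardize_rows,
)
from epimodule.quantify import quantify_counts


def _matrix(values, coverage=None, **kw):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    defaults = dict(
        site_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{i}" for i in range(n)],
        samples=[f"c{j}" for j in range(s)],
        values=values,
        coverage=np.zeros_like(values, dtype=int)
        if coverage is None
        else np.asarray(coverage),
        scale="m",
    )
    defaults.update(kw)
    return MethylationMatrix(**defaults)


class TestMergeReplicates:
    def test_single_replicate_per_condition_is_identity(self, replicate_counts):
        rc = replicate_counts
        rc.condition_of_replicate = {"a1": "A", "a2": "B", "b1": "C", "b2": "D"}
        merged = merge_replicates(rc)
        np.testing.assert_array_equal(merged.t, rc.t)
        np.testing.assert_array_equal(merged.c, rc.c)

    def test_two_replicates_sum_elementwise(self, replicate_counts):
        merged = merge_replicates(replicate_counts)
        assert merged.samples == ["A", "B"]
        # column A sums t columns [3,4] and [1,6] -> [4,10]
        np.testing.assert_array_equal(merged.t[:, 0], [4, 10])
        np.testing.assert_array_equal(merged.t[:, 1], [9, 5])
        np.testing.assert_array_equal(merged.c[:, 0], [4, 3])

    def test_unknown_condition_and_empty_condition_raise(self, replicate_counts):
        replicate_counts.condition_of_replicate = {"a1": "A", "a2": "A", "b1": "B"}
        with pytest.raises(ValueError, match="no condition assignment"):
            merge_replicates(replicate_counts)
        replicate_counts.condition_of_replicate = {
            "a1": "A", "a2": "A", "b1": "B", "b2": "B",
        }
        with pytest.raises(ValueError, match="zero replicates"):
            merge_replicates(replicate_counts, conditions=["A", "B", "C"])


class TestSizeFactors:
    def test_equal_totals_give_unit_factors(self):
        cs = MeripCountSet(
            site_ids=["s1"], gene_ids=["g"], samples=["c1", "c2"],
            t=np.array([[5, 5]]), c=np.array([[3, 3]]),
        )
        out = estimate_size_factors(cs)
        np.testing.assert_allclose(out.d_t, [1, 1])
        np.testing.assert_allclose(out.d_c, [1, 1])

    def test_factors_are_totals_over_mean(self):
        cs = MeripCountSet(
            site_ids=["s1"], gene_ids=["g"], samples=["c1", "c2"],
            t=np.array([[1_000_000, 3_000_000]]),
            c=np.array([[2_000_000, 2_000_000]]),
        )
        out = estimate_size_factors(cs)
        np.testing.assert_allclose(out.d_t, [0.5, 1.5])
        np.testing.assert_allclose(out.d_c, [1.0, 1.0])

    def test_zero_total_column_raises(self):
        cs = MeripCountSet(
            site_ids=["s1"], gene_ids=["g"], samples=["c1", "c2"],
            t=np.array([[0, 5]]), c=np.array([[1, 1]]),
        )
        with pytest.raises(ValueError, match="all-zero IP"):
            estimate_size_factors(cs)


class TestMethylationLevel:
    @pytest.mark.parametrize(
        "t, c, expected",
        [(100, 0, 1.0), (1, 0, 1.0), (0, 7, 0.0), (5, 5, 0.5)],
    )
    def test_worked_examples(self, t, c, expected):
        assert methylation_level(t, c, 1.0, 1.0) == pytest.approx(expected)

    def test_zero_coverage_returns_uninformative_midpoint(self):
        assert methylation_level(0, 0) == 0.5

    def test_reduces_to_simple_fraction_under_equal_factors(self):
        t, c = 7, 13
        assert methylation_level(t, c, 2.5, 2.5) == pytest.approx(t / (t + c))

    def test_size_factors_rescale_counts(self):
        # halving IP depth doubles the effective IP count
        assert methylation_level(5, 10, d_t=0.5, d_c=1.0) == pytest.approx(
            10 / (10 + 10)
        )

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            methylation_level(-1, 2)

    @given(
        t=st.integers(0, 10_000),
        c=st.integers(0, 10_000),
        dt=st.floats(0.1, 10),
        dc=st.floats(0.1, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone_in_t(self, t, c, dt, dc):
        m = methylation_level(t, c, dt, dc)
        assert 0.0 <= m <= 1.0
        if t + c > 0:
            assert methylation_level(t + 1, c, dt, dc) >= m


class TestMValue:
    def test_symmetric_counts_give_zero(self):
        assert m_value(8, 8, 1, 1) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert m_value(4, 0, 1, 1, eps=0.5) == pytest.approx(np.log2(9))

    def test_antisymmetric_under_ip_input_swap(self):
        assert m_value(3, 11) == pytest.approx(-m_value(11, 3))

    def test_invalid_eps_raises(self):
        with pytest.raises(ValueError, match="eps"):
            m_value(1, 1, eps=0.0)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        mat = _matrix([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0]])
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out.values, mat.values)

    def test_rank_and_average_by_hand(self):
        mat = _matrix([[1.0, 8.0], [3.0, 2.0]])
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out.values, [[1.5, 5.5], [5.5, 1.5]])

    def test_sorted_columns_identical_and_ranks_preserved(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(40, 4))
        out = quantile_normalize(_matrix(X))
        ref = np.sort(out.values[:, 0])
        for j in range(4):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)
            orig = np.argsort(X[:, j], kind="stable")
            new = np.argsort(out.values[:, j], kind="stable")
            np.testing.assert_array_equal(orig, new)

    def test_ties_receive_mean_of_reference(self):
        mat = _matrix([[1.0, 4.0], [1.0, 2.0]])
        out = quantile_normalize(mat)
        # tied column gets the mean of the two reference values in both rows
        assert out.values[0, 0] == pytest.approx(out.values[1, 0])


class TestSelectDynamicSites:
    def test_keep_everything_preserves_order(self):
        mat = _matrix(np.arange(8.0).reshape(4, 2))
        out = select_dynamic_sites(mat, n_by_mean=10, n_by_variance=10)
        np.testing.assert_array_equal(out.site_ids, mat.site_ids)
        np.testing.assert_allclose(out.values, mat.values)

    def test_two_stage_hand_example(self):
        # means: s0=0.9 s1=0.8 s2=0.2 s3=0.5 ; top2 by mean = {s0, s1}
        # variances among those: s0 tiny, s1 large -> keep s1
        mat = _matrix(
            [[0.9, 0.9], [0.6, 1.0], [0.2, 0.2], [0.5, 0.5]],
        )
        out = select_dynamic_sites(mat, n_by_mean=2, n_by_variance=1)
        assert list(out.site_ids) == ["s1"]

    def test_defaults_echo_tuned_selection_sizes(self):
        import inspect

        sig = inspect.signature(select_dynamic_sites)
        assert sig.parameters["n_by_mean"].default == 20000
        assert sig.parameters["n_by_variance"].default == 10000

    def test_invalid_sizes_raise(self):
        mat = _matrix([[0.1, 0.2]])
        with pytest.raises(ValueError):
            select_dynamic_sites(mat, n_by_mean=0)
        with pytest.raises(ValueError):
            select_dynamic_sites(mat, n_by_mean=5, n_by_variance=6)


class TestStandardizeRows:
    def test_sample_sd_hand_example(self):
        out = standardize_rows(_matrix([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]])

    def test_idempotent_on_standardized_rows(self):
        out1 = standardize_rows(_matrix([[1.0, 5.0, 3.0], [2.0, 0.0, 4.0]]))
        out2 = standardize_rows(out1)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-12)

    def test_rows_have_zero_mean_unit_sample_sd(self):
        rng = np.random.default_rng(3)
        out = standardize_rows(_matrix(rng.normal(size=(20, 5))))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_constant_row_error_names_site(self):
        with pytest.raises(ValueError, match="s1"):
            standardize_rows(_matrix([[1.0, 2.0], [4.0, 4.0]], site_ids=["s0", "s1"]))


class TestPipeline:
    def test_full_pipeline_is_deterministic(self, replicate_counts):
        a = preprocess(replicate_counts, n_by_mean=2, n_by_variance=2)
        b = preprocess(replicate_counts, n_by_mean=2, n_by_variance=2)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.coverage, b.coverage)
        assert a.stage == "standardized" and a.scale == "z"

    def test_coverage_tracks_subsetting(self, small_counts):
        mat = quantify_counts(small_counts)
        sel = select_dynamic_sites(mat, n_by_mean=3, n_by_variance=2)
        assert sel.values.shape == sel.coverage.shape == (2, 3)
        for sid in sel.site_ids:
            i_old = list(small_counts.site_ids).index(sid)
            i_new = list(sel.site_ids).index(sid)
            np.testing.assert_array_equal(
                sel.coverage[i_new], small_counts.coverage[i_old]
            )
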
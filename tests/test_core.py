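import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import random_test_signals
from mcsampen import (
    chebyshev_distance,
    direct_range_count,
    match_counts,
    normalize_signal,
    sample_entropy_exact,
)


class TestChebyshevDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([0, 0], [0, 0], 0.0),
            ([1, 2], [2, 0], 2.0),
            ([0.1, 0.4, 0.2], [0.1, 0.1, 0.2], 0.3),
        ],
    )
    def test_examples(self, a, b, expected):
        assert chebyshev_distance(a, b) == pytest.approx(expected)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            chebyshev_distance([1, 2], [1, 2, 3])

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=8),
        st.lists(st.floats(-100, 100), min_size=1, max_size=8),
    )
    @settings(derandomize=True, max_examples=60)
    def test_symmetry_and_identity(self, a, b):
        if len(a) == len(b):
            d = chebyshev_distance(a, b)
            assert d == chebyshev_distance(b, a)
            assert d >= 0
            assert (d == 0) == (a == b)
        assert chebyshev_distance(a, a) == 0


class TestNormalize:
    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            normalize_signal(np.ones(20))

    def test_unit_sd_input_unchanged(self):
        u = np.tile([-1.0, 1.0], 10)
        out = normalize_signal(u)
        np.testing.assert_allclose(out.values, u)

    def test_output_sd_is_one_without_centering(self, rng):
        u = rng.standard_normal(500) + 10.0
        out = normalize_signal(u)
        assert out.sd == pytest.approx(1.0, abs=1e-12)
        # no centering: mean/sd ratio preserved
        assert out.values.mean() == pytest.approx(u.mean() / u.std())


class TestDirectRangeCount:
    def test_toy_length_one_templates(self, toy_signal):
        assert direct_range_count(toy_signal, range(5), 1, 0.5) == 6

    def test_toy_length_two_templates(self, toy_signal):
        assert direct_range_count(toy_signal, range(5), 2, 0.5) == 2

    def test_singleton_has_no_pairs(self, toy_signal):
        assert direct_range_count(toy_signal, [2], 1, 0.5) == 0

    def test_out_of_range_index_rejected(self, toy_signal):
        with pytest.raises(ValueError):
            direct_range_count(toy_signal, [0, 99], 1, 0.5)

    def test_duplicate_indices_rejected(self, toy_signal):
        with pytest.raises(ValueError):
            direct_range_count(toy_signal, [1, 1], 1, 0.5)


class TestMatchCounts:
    def test_toy_counts_and_per_template(self, toy_signal):
        mc = match_counts(toy_signal, 1, 0.5)
        assert (mc.a, mc.b) == (6, 2)
        np.testing.assert_array_equal(mc.per_template_a, [3, 3, 0, 3, 3])
        np.testing.assert_array_equal(mc.per_template_b, [1, 1, 0, 1, 1])

    def test_constant_signal_all_pairs_match(self):
        mc = match_counts(np.ones(10), 2, 0.1)
        assert mc.n_templates == 7
        assert mc.a == mc.b == 7 * 6 // 2

    def test_big_steps_never_match(self):
        mc = match_counts(np.arange(10.0) * 5, 1, 0.2)
        assert mc.a == mc.b == 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            match_counts([1.0, 2.0, 3.0], 1, 0.5)

    def test_agrees_with_bruteforce(self):
        for u in random_test_signals(24, 80):
            for m in (1, 2, 3):
                for r in (0.1, 0.2, 0.5):
                    mc = match_counts(u, m, r)
                    a_i, b_i = oracles.brute_per_template_counts(u, m, r)
                    np.testing.assert_array_equal(mc.per_template_a, a_i)
                    np.testing.assert_array_equal(mc.per_template_b, b_i)

    def test_counts_monotone_in_tolerance(self):
        for u in random_test_signals(6, 60, seed=99):
            prev_a = prev_b = -1
            for r in (0.05, 0.1, 0.2, 0.5, 1.0):
                mc = match_counts(u, 2, r)
                assert mc.a >= prev_a and mc.b >= prev_b
                prev_a, prev_b = mc.a, mc.b

    def test_b_never_exceeds_a(self):
        for u in random_test_signals(12, 60, seed=3):
            mc = match_counts(u, 2, 0.3)
            assert mc.b <= mc.a
            assert np.all(mc.per_template_b <= mc.per_template_a)


class TestSampleEntropyExact:
    def test_toy_value_is_log_three(self, toy_signal):
        res = sample_entropy_exact(toy_signal, 1, 0.5)
        assert res.value == pytest.approx(math.log(3))
        assert (res.a, res.b, res.degenerate) == (6, 2, False)

    def test_constant_signal_zero_entropy(self):
        res = sample_entropy_exact(np.ones(10), 1, 0.1)
        assert res.value == 0.0
        assert not res.degenerate

    def test_degenerate_fallback_value(self):
        # steps of 5 with r=0.2: no matches at any length, N = 8
        res = sample_entropy_exact(np.arange(10.0) * 5, 1, 0.2)
        assert res.degenerate
        assert res.value == pytest.approx(-math.log(2 / (8 * 7)))

    def test_scale_covariance(self, rng):
        u = rng.standard_normal(120)
        for c in (0.25, 3.0, 17.5):
            base = sample_entropy_exact(u, 2, 0.2)
            scaled = sample_entropy_exact(c * u, 2, c * 0.2)
            assert scaled.value == pytest.approx(base.value)
            assert (scaled.a, scaled.b) == (base.a, base.b)

    def test_matches_bruteforce_definition(self):
        for u in random_test_signals(10, 60, seed=7):
            for m in (1, 2):
                got = sample_entropy_exact(u, m, 0.25)
                assert got.value == pytest.approx(oracles.brute_entropy(u, m, 0.25))
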
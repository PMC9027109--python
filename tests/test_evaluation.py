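import math

import numpy as np
import pytest

from mcsampen import (
    comparison_counter,
    convergence_surface,
    error_metrics,
    mcsampen,
    predicted_comparison_count,
    relative_error_vs_p,
)
from mcsampen.evaluation import N0_GRID, N1_GRID, schedule_n0, schedule_n1
from mcsampen.signals import mix_process


class TestErrorMetrics:
    def test_perfect_estimates(self):
        rep = error_metrics([2.0, 2.0, 2.0], 2.0)
        assert rep.mean_err == 0.0 and rep.rmse == 0.0

    def test_symmetric_errors_cancel_in_mean_not_rmse(self):
        rep = error_metrics([1.9, 2.1, 1.9, 2.1], 2.0)
        assert rep.mean_err == pytest.approx(0.0, abs=1e-15)
        assert rep.rmse == pytest.approx(0.1)

    def test_two_point_example(self):
        rep = error_metrics([1.0, 3.0], 1.0)
        assert rep.mean_err == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(math.sqrt(2))
        assert rep.relative_error == pytest.approx(math.sqrt(2))

    def test_zero_truth_has_no_relative_error(self):
        assert error_metrics([0.1], 0.0).relative_error is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            error_metrics([], 1.0)

    def test_rmse_dominates_bias(self, rng):
        est = rng.normal(1.0, 0.3, size=200)
        rep = error_metrics(est, 0.8)
        assert rep.rmse >= rep.mean_err


class TestComparisonCounting:
    def test_tiny_run_counted_exactly(self, rng):
        u = mix_process(200, 0.5, rng=rng)
        est = mcsampen(u, 2, 0.2, n0=3, n1=2, rng=0)
        assert comparison_counter(est) == 12
        assert predicted_comparison_count(3, 2) == 12

    def test_count_independent_of_series_length(self, rng):
        est_a = mcsampen(mix_process(512, 0.5, rng=1), 2, 0.2, n0=40, n1=5, rng=0)
        est_b = mcsampen(mix_process(4096, 0.5, rng=2), 2, 0.2, n0=40, n1=5, rng=0)
        assert comparison_counter(est_a) == comparison_counter(est_b)
        assert comparison_counter(est_a) == predicted_comparison_count(40, 5)

    def test_zero_experiments_disallowed(self):
        with pytest.raises(ValueError):
            predicted_comparison_count(10, 0)

    def test_counting_requires_instrumented_run(self):
        with pytest.raises(TypeError):
            comparison_counter(3.14)


class TestConvergenceSurface:
    def test_full_subsample_cell_has_zero_error(self, rng):
        u = mix_process(200, 0.5, rng=rng)
        N = u.template_count(2)
        table = convergence_surface(u, 2, 0.2, [N], [3], runs=2, rng=0)
        assert len(table) == 1
        assert table["rmse"].iloc[0] == pytest.approx(0.0, abs=1e-14)

    def test_oversized_cells_skipped(self, rng, caplog):
        u = mix_process(200, 0.5, rng=rng)
        table = convergence_surface(u, 2, 0.2, [50, 10_000], [2, 4], runs=2, rng=0)
        assert len(table) == 2  # one n0 survives x two n1 values
        assert set(table["n0"]) == {50}

    def test_row_count_is_grid_product(self, rng):
        u = mix_process(400, 0.5, rng=rng)
        table = convergence_surface(u, 2, 0.2, [20, 40], [2, 3, 4], runs=2, rng=0)
        assert len(table) == 6
        assert list(table.columns) == ["n0", "n1", "mean_err", "rmse", "runs"]

    def test_published_grid_presets(self):
        assert N0_GRID[0] == 200 and N0_GRID[-1] == 4000 and len(N0_GRID) == 20
        assert N1_GRID[0] == 10 and N1_GRID[-1] == 250 and len(N1_GRID) == 25


class TestRelativeErrorVsP:
    def test_schedule_formulas(self):
        assert schedule_n0(0.0) == 1000 and schedule_n1(0.0) == 80
        assert schedule_n0(0.5) == 2500 and schedule_n1(0.5) == 115
        assert schedule_n0(0.9) == 3700 and schedule_n1(0.9) == 143
        # nondecreasing in p
        grid = np.linspace(0, 1, 11)
        assert all(
            schedule_n0(a) <= schedule_n0(b) for a, b in zip(grid[:-1], grid[1:])
        )

    def test_single_p_row_small_scale(self):
        table = relative_error_vs_p([0.3], n=2**13, runs=3, rng=4)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["n0"] == schedule_n0(0.3) and row["n1"] == schedule_n1(0.3)
        assert row["relative_error"] > 0
        assert not row["flagged"]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            relative_error_vs_p([1.2], n=2**10, runs=2, rng=0)

    def test_deterministic_given_seed(self):
        a = relative_error_vs_p([0.5], n=2**12, runs=2, rng=8)
        b = relative_error_vs_p([0.5], n=2**12, runs=2, rng=8)
        assert a.equals(b)
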
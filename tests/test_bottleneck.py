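"""Binomial colonization bottleneck and survival-probability inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorclones.bottleneck import (
    InfeasibleInferenceError,
    aggregate_observation_curve,
    apply_bottleneck,
    binned_observation_curve,
    calibrate_q_vs_B,
    expected_surviving,
    fit_power_law_map,
    founder_pmf,
    infer_q,
    observation_probability,
)
from tumorclones.dynamics import SimulationParams
from tumorclones.seeding import stream


class TestFounderPmf:
    def test_certain_survival(self):
        assert founder_pmf(17, 1.0, 17) == pytest.approx(1.0)

    def test_pmf_sums_to_one(self):
        x = np.arange(0, 201)
        assert founder_pmf(200, 0.013, x).sum() == pytest.approx(1.0, abs=1e-12)

    def test_stable_at_large_founder_counts(self):
        # binomial with n=1e7 must not overflow; mass concentrates near n*q
        n, q = 10_000_000, 2.6e-3
        center = int(n * q)
        x = np.arange(center - 2000, center + 2000)
        p = founder_pmf(n, q, x)
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-4)

    def test_rejects_x_out_of_range(self):
        with pytest.raises(ValueError):
            founder_pmf(10, 0.5, 11)


class TestApplyBottleneck:
    def test_closed_ends(self):
        n = np.array([5, 100, 0, 17])
        assert apply_bottleneck(n, 0.0, 0).sum() == 0
        np.testing.assert_array_equal(apply_bottleneck(n, 1.0, 0), n)

    def test_survivors_bounded_by_founders(self):
        n = np.arange(50)
        s = apply_bottleneck(n, 0.4, 1)
        assert np.all(s <= n) and np.all(s >= 0)

    def test_mean_survivor_count_matches_expectation(self, small_library):
        # Monte-Carlo mean of barcodes with >= 1 survivor vs the analytic
        # expected-survivor sum, within 3 standard errors
        cells = small_library.cell_counts()
        q = 0.01
        reps = 300
        obs = np.array([
            np.count_nonzero(apply_bottleneck(cells, q, stream(7, "mc", i)))
            for i in range(reps)
        ])
        p_obs = observation_probability(small_library.frequencies,
                                        small_library.total_cells, q)
        expected = p_obs.sum()
        se = np.sqrt(np.sum(p_obs * (1 - p_obs)) / reps)
        assert abs(obs.mean() - expected) <= 3 * se


class TestObservationProbability:
    def test_zero_frequency_never_observed(self):
        assert observation_probability(0.0, 1e6, 0.5) == 0.0

    def test_complement_of_empty_founder_cell(self):
        # 100 inoculum cells at q=2.6e-3: observed with prob 1 - 77% = 23%
        p = observation_probability(100 / 5e6, 5e6, 2.6e-3)
        assert p == pytest.approx(1 - founder_pmf(100, 2.6e-3, 0), rel=1e-9)
        assert p == pytest.approx(0.23, abs=0.005)

    def test_certain_at_q_one(self):
        assert observation_probability(1e-6, 5e6, 1.0) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        f=st.floats(1e-8, 1e-2),
        N=st.floats(1e3, 1e8),
        q=st.floats(1e-6, 0.99),
        bump=st.floats(1.01, 10.0),
    )
    def test_monotone_in_each_argument(self, f, N, q, bump):
        base = observation_probability(f, N, q)
        assert observation_probability(min(f * bump, 1.0), N, q) >= base
        assert observation_probability(f, N * bump, q) >= base
        assert observation_probability(f, N, min(q * bump, 1.0)) >= base


class TestExpectedSurviving:
    def test_ends(self, small_library):
        f, N = small_library.frequencies, small_library.total_cells
        assert expected_surviving(f, N, 0.0) == 0.0
        n_with_cells = int(np.count_nonzero(small_library.cell_counts() >= 1))
        assert expected_surviving(f, N, 1.0) == pytest.approx(n_with_cells)

    def test_uniform_closed_form(self):
        # 40,000 barcodes at f=1/40000, N=5e6, q=2.6e-3
        n, N, q = 40_000, 5e6, 2.6e-3
        f = np.full(n, 1.0 / n)
        expected = n * (1 - (1 - q) ** (N / n))
        assert expected_surviving(f, N, q) == pytest.approx(expected, rel=1e-9)

    def test_single_barcode_equals_observation_probability(self):
        assert expected_surviving([1.0], 100, 2.6e-3) == pytest.approx(
            observation_probability(1.0, 100, 2.6e-3)
        )


class TestInferQ:
    def test_round_trip_is_identity(self, small_library):
        f, N = small_library.frequencies, small_library.total_cells
        q_true = 2.6e-3
        B = expected_surviving(f, N, q_true)
        assert infer_q(f, N, B) == pytest.approx(q_true, rel=1e-6)

    def test_small_observed_count_gives_small_q(self, small_library):
        f, N = small_library.frequencies, small_library.total_cells
        assert infer_q(f, N, 1e-3) < 1e-7

    def test_infeasible_count_raises_with_bound(self, small_library):
        f, N = small_library.frequencies, small_library.total_cells
        with pytest.raises(InfeasibleInferenceError, match="attainable range"):
            infer_q(f, N, len(small_library) + 1)
        with pytest.raises(InfeasibleInferenceError):
            infer_q(f, N, 0.0)

    def test_monotone_in_observed_count(self, small_library):
        f, N = small_library.frequencies, small_library.total_cells
        qs = [infer_q(f, N, B) for B in (10, 100, 500)]
        assert qs[0] < qs[1] < qs[2]


class TestAggregationCurve:
    def test_group_size_one_is_raw_presence(self, small_library):
        f, N = small_library.frequencies, small_library.total_cells
        present = apply_bottleneck(small_library.cell_counts(), 0.01, 3) > 0
        curve = aggregate_observation_curve(f, present, [1], N, 0.01, seed=0)
        assert len(curve) == len(small_library)
        assert curve["observed"].sum() == present.sum()

    def test_single_group_of_everything(self, small_library):
        f, N = small_library.frequencies, small_library.total_cells
        present = np.zeros(len(small_library), dtype=bool)
        present[3] = True
        curve = aggregate_observation_curve(f, present, [len(small_library)], N, 0.5, seed=0)
        assert len(curve) == 1
        assert curve["frequency"].iloc[0] == pytest.approx(1.0)
        assert curve["observed"].iloc[0] == 1

    def test_oversized_group_rejected(self, small_library):
        f, N = small_library.frequencies, small_library.total_cells
        with pytest.raises(ValueError, match="exceeds"):
            aggregate_observation_curve(f, np.zeros(len(f), bool),
                                        [len(f) + 1], N, 0.1)

    def test_empirical_matches_prediction_across_bins(self, small_library):
        # Monte-Carlo observation fractions track 1-(1-q)^(N*f) within 0.05
        f, N = small_library.frequencies, small_library.total_cells
        q = 2.6e-3
        present = apply_bottleneck(small_library.cell_counts(), q, 11) > 0
        curve = aggregate_observation_curve(
            f, present, [1, 2, 4, 8, 16, 32, 64], N, q, seed=5
        )
        binned = binned_observation_curve(curve, n_bins=8)
        gaps = (binned["observed_fraction"] - binned["predicted"]).abs()
        assert gaps.mean() < 0.05


class TestCalibration:
    def test_noiseless_power_law_recovered_exactly(self):
        q = np.array([1e-4, 1e-3, 1e-2, 1e-1])
        fit = fit_power_law_map(q, 200.0 * q**0.9)
        assert fit.a == pytest.approx(200.0, rel=1e-6)
        assert fit.b == pytest.approx(0.9, rel=1e-6)

    def test_inversion_identity_on_curve(self):
        q = np.array([1e-4, 1e-3, 1e-2])
        fit = fit_power_law_map(q, 150.0 * q**0.85)
        for q_star in (3e-4, 2e-3):
            assert fit.invert(fit.predict(q_star)) == pytest.approx(q_star, rel=1e-9)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_power_law_map([1e-3, 2e-3, 4e-3], [50.0, 50.0, 50.0])

    def test_end_to_end_day1_inversion_recovers_q(self, small_library):
        # full dynamics: calibrate B = a*q^b on a grid, then invert the
        # day-1 survivor count of an off-grid q; recovery within 30%
        params = SimulationParams()
        fit = calibrate_q_vs_B(
            params, q_grid=[1e-3, 2.6e-3, 6e-3], n_reps=1, seed=13,
            library=small_library,
        )
        from tumorclones.synthetic import simulate_experiment

        q_star = 2.0e-3
        bundle = simulate_experiment(
            small_library, params, q=q_star, n_tumors=1, sample_days=[24.0],
            depth=100_000, seed=99,
        )
        B_day1 = int(np.count_nonzero(bundle.trajectories[0].final_abundances >= 1.0))
        assert fit.invert(B_day1) == pytest.approx(q_star, rel=0.30)
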
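"""Spike-count statistics: Poisson significance, selectivity,
habituation, recovery, receptive-field size, latency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from scsift import metrics as mx


def poisson_upper_tail(r, lam, tol=1e-18):
    """Independent oracle: direct tail sum P(X >= r) for X~Poisson."""
    if r <= 0:
        return 1.0
    # start from the pmf at r and accumulate upward
    log_pmf = -lam + r * math.log(lam) - math.lgamma(r + 1)
    term = math.exp(log_pmf)
    total, k = 0.0, r
    while term > tol * max(total, term):
        total += term
        k += 1
        term *= lam / k
    return total


class TestBackgroundActivity:
    def test_rate_times_duration(self):
        spikes = np.linspace(0.25, 9.75, 20)  # 20 spikes in 10 s
        mu, trunc = mx.background_activity(spikes, onset=10.0, duration=0.5, window=10.0)
        assert mu == pytest.approx(1.0)
        assert not trunc

    def test_empty_window_gives_zero(self):
        mu, _ = mx.background_activity(np.array([20.0]), onset=10.0, duration=1.0)
        assert mu == 0.0

    def test_linear_in_duration_and_truncation_flag(self):
        spikes = np.arange(0.5, 3.0, 0.5)
        mu1, t1 = mx.background_activity(spikes, onset=3.0, duration=1.0, window=5.0)
        mu2, _ = mx.background_activity(spikes, onset=3.0, duration=2.0, window=5.0)
        assert mu2 == pytest.approx(2 * mu1)
        assert t1  # the 5 s window reaches before the recording start


class TestPoissonResponseTest:
    def test_zero_count_never_significant(self):
        res = mx.poisson_response_test(0, 5.0)
        assert res.p == 1.0 and not res.significant

    def test_worked_values_at_the_floor(self):
        # background below one spike: the model mean is floored at 1
        res5 = mx.poisson_response_test(5, 0.5)
        assert res5.lambda_used == 1.0
        assert res5.p == pytest.approx(1 - math.exp(-1) * (1 + 1 + 0.5 + 1 / 6 + 1 / 24), rel=1e-10)
        assert res5.p == pytest.approx(0.00366, abs=5e-5)
        assert res5.significant
        res4 = mx.poisson_response_test(4, 0.5)
        assert res4.p == pytest.approx(0.0190, abs=5e-4)
        assert not res4.significant

    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.5, 7.0, 20.0])
    def test_agrees_with_tail_sum_oracle(self, lam):
        for r in range(0, 51, 5):
            mu = lam if lam >= 1 else 0.2
            res = mx.poisson_response_test(r, lam)
            oracle = poisson_upper_tail(r, res.lambda_used)
            assert res.p == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    def test_null_calibration_is_conservative(self, rng):
        """Under pure baseline firing the false-positive rate stays at
        or below the nominal alpha (discrete counts make it
        conservative)."""
        mu = 2.0
        counts = rng.poisson(mu, size=10000)
        frac = np.mean([mx.poisson_response_test(int(c), mu).significant for c in counts])
        se = np.sqrt(0.005 * 0.995 / 10000)
        assert frac <= 0.005 + 3 * se

    def test_bonferroni(self):
        assert mx.bonferroni_alpha(0.005, 1) == 0.005
        assert mx.bonferroni_alpha(0.005, 100) == pytest.approx(5e-5)
        alphas = [mx.bonferroni_alpha(0.005, n) for n in range(1, 20)]
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))


class TestSelectivity:
    def test_equal_responses_give_zero(self):
        res = mx.selectivity_index(10, 0.0, 10, 0.0)
        assert res.index == 0.0

    def test_silent_comparison_gives_one(self):
        res = mx.selectivity_index(10, 0.0, 0, 0.0)
        assert res.index == 1.0

    @given(
        rl=hs.integers(5, 60),
        ro=hs.integers(5, 60),
        mu=hs.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_stimulus_swap(self, rl, ro, mu):
        a = mx.selectivity_index(rl, mu, ro, mu)
        b = mx.selectivity_index(ro, mu, rl, mu)
        if a.index is not None and b.index is not None:
            assert a.index == pytest.approx(-b.index)

    def test_excluded_when_neither_significant(self):
        res = mx.selectivity_index(1, 0.5, 0, 0.5)
        assert not res.included and res.index is None

    def test_checkerboard_variant_formula(self):
        res = mx.selectivity_vs_checkerboard(20, 1.0, mean_checker_rate_hz=4.0, loom_duration=0.75)
        r_l, r_o = 20 - 1.0, 4.0 * 0.75 - 1.0
        assert res.index == pytest.approx((r_l - r_o) / (r_l + r_o))

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_scale_invariance(self, k):
        base = mx.selectivity_index(20, 2.0, 8, 2.0)
        scaled = mx.selectivity_index(20 * k, 2.0 * k, 8 * k, 2.0 * k)
        assert scaled.index == pytest.approx(base.index)


class TestHabituation:
    def test_complete_habituation_is_one(self):
        counts = [20] + [0] * 9
        assert mx.habituation_index(counts, 0.0).index == 1.0

    def test_no_habituation_is_zero(self):
        counts = [20] * 10
        assert mx.habituation_index(counts, 0.0).index == 0.0

    def test_facilitation_is_negative_one(self):
        counts = [20] + [0] * 8 + [40]
        assert mx.habituation_index(counts, 0.0).index == -1.0

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_scale_invariance(self, k):
        counts = np.array([24, 12, 9, 6, 6, 6, 6, 6, 6, 6])
        a = mx.habituation_index(counts, 2.0)
        b = mx.habituation_index(counts * k, 2.0 * k)
        assert b.index == pytest.approx(a.index)

    def test_insignificant_first_response_excluded(self):
        res = mx.habituation_index([2, 1, 0, 0, 0, 0, 0, 0, 0, 0], 1.5)
        assert not res.included

    def test_alternative_repeat_indices(self):
        counts = [20, 10, 8, 5, 5, 5, 4, 4, 4, 2]
        for i in (4, 7, 10):
            res = mx.habituation_index(counts, 0.0, i=i)
            assert res.index == pytest.approx(1 - counts[i - 1] / counts[0])


class TestRecovery:
    def test_identical_counts_recover_fully(self):
        res = mx.recovery_curve([20] * 8, 0.0)
        np.testing.assert_allclose(res.fractions, 1.0)

    def test_silent_after_first_gives_zero(self):
        res = mx.recovery_curve([20] + [0] * 7, 0.0)
        np.testing.assert_allclose(res.fractions[1:], 0.0)

    def test_population_percentiles(self):
        fr = np.array([[1, 0.2, 0.6], [1, 0.4, 0.8], [1, 0.6, 1.0]])
        q = mx.recovery_percentiles(fr)
        assert q.shape == (3, 3)
        assert q[1, 1] == pytest.approx(0.4)  # median of the second event


class TestRFSize:
    def grid(self):
        from scsift.stimuli import grid_locations

        return grid_locations()

    def test_single_location_responder_has_grid_resolution_size(self):
        grid = self.grid()
        counts = [[0]] * 12 + [[30]] + [[0]] * 12
        mus = [[0.0]] * 25
        est = mx.rf_size(counts, mus, grid, spacing=15.0)
        assert est.mean_radial_distance == 0.0
        assert est.size == 15.0

    def test_two_equal_responses_30_deg_apart(self):
        grid = np.array([[-15.0, 0.0], [15.0, 0.0]])
        est = mx.rf_size([[30], [30]], [[0.0], [0.0]], grid, spacing=15.0)
        np.testing.assert_allclose(est.center, [0.0, 0.0])
        assert est.mean_radial_distance == pytest.approx(15.0)
        assert est.size == pytest.approx(45.0)

    def test_uniform_response_over_grid_matches_exhaustive_sum(self):
        grid = self.grid()
        counts = [[40]] * 25
        mus = [[0.0]] * 25
        est = mx.rf_size(counts, mus, grid, spacing=15.0)
        # exhaustive oracle over the 25 coordinates
        center = grid.mean(axis=0)
        delta = np.mean(np.linalg.norm(grid - center, axis=1))
        assert est.size == pytest.approx(2 * delta + 15.0)

    def test_translation_equivariance(self):
        grid = self.grid()
        counts = [[c] for c in np.arange(25) % 7 * 10]
        mus = [[0.0]] * 25
        a = mx.rf_size(counts, mus, grid)
        b = mx.rf_size(counts, mus, grid + np.array([40.0, -25.0]))
        np.testing.assert_allclose(b.center, a.center + [40.0, -25.0])
        assert b.mean_radial_distance == pytest.approx(a.mean_radial_distance)
        assert b.size == pytest.approx(a.size)

    def test_no_significant_location_excluded(self):
        grid = self.grid()
        est = mx.rf_size([[1]] * 25, [[0.5]] * 25, grid)
        assert not est.included


class TestLatency:
    def test_constant_latency_has_zero_sd(self):
        onsets = np.arange(5) * 10.0
        # five spikes per trial: comfortably significant at lambda = 1
        offsets = [0.05, 0.2, 0.3, 0.4, 0.5]
        spikes = np.sort(np.concatenate([onsets + o for o in offsets]))
        res = mx.latency_stats(spikes, onsets, np.full(5, 0.75), np.zeros(5))
        assert res.included
        np.testing.assert_allclose(res.latencies, 0.05)
        assert res.sd == pytest.approx(0.0)

    def test_pre_30ms_spikes_excluded(self):
        onsets = np.arange(5) * 10.0
        offsets = [0.01, 0.08, 0.2, 0.3, 0.4]
        spikes = np.sort(np.concatenate([onsets + o for o in offsets]))
        res = mx.latency_stats(spikes, onsets, np.full(5, 0.75), np.zeros(5))
        np.testing.assert_allclose(res.latencies, 0.08)

    def test_sample_sd_of_three_latencies(self):
        onsets = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        lat = [0.05, 0.07, 0.09, 0.07, 0.07]
        spikes = np.sort(
            np.concatenate(
                [onsets + lat] + [onsets + o for o in (0.2, 0.3, 0.4, 0.5)]
            )
        )
        res = mx.latency_stats(spikes, onsets, np.full(5, 0.75), np.zeros(5))
        # the first three latencies alone have sample SD 0.02 (ddof=1)
        assert np.std([0.05, 0.07, 0.09], ddof=1) == pytest.approx(0.02)
        assert res.sd == pytest.approx(np.std(lat, ddof=1))

    def test_high_background_excluded(self):
        onsets = np.arange(5) * 10.0
        spikes = np.sort(np.concatenate([onsets + k * 0.04 for k in range(1, 10)]))
        res = mx.latency_stats(spikes, onsets, np.full(5, 0.75), np.full(5, 2.0))
        assert not res.included and "background" in res.reason

    def test_too_few_significant_trials_excluded(self):
        onsets = np.arange(5) * 10.0
        spikes = onsets[:2] + 0.05  # responds on two trials only
        res = mx.latency_stats(np.sort(spikes), onsets, np.full(5, 0.75), np.zeros(5))
        assert not res.included
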
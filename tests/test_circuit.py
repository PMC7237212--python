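"""Circuit model: kernels, LN units, looming detectors, synaptic
depression, and the full widefield simulation."""

import numpy as np
import pytest

from scsift import circuit as cm
from scsift import stimuli as st


class TestTemporalKernel:
    def test_zero_at_origin_and_causal(self):
        assert cm.eval_temporal_kernel(cm.CENTER_TEMPORAL, 0.0) == 0.0
        assert cm.eval_temporal_kernel(cm.CENTER_TEMPORAL, -0.1) == 0.0

    def test_first_lobe_peaks_at_one(self):
        # at t = tau1 the positive lobe is exactly (1)^n exp(0) = 1
        p = cm.CENTER_TEMPORAL
        second = p.b * (p.tau1 / p.tau2) ** p.n2 * np.exp(-p.n2 * (p.tau1 / p.tau2 - 1))
        assert cm.eval_temporal_kernel(p, p.tau1) == pytest.approx(1.0 - second, rel=1e-12)

    def test_center_kernel_scalar_oracle(self):
        # direct scalar evaluation with the tabulated center parameters
        t = 0.104
        expected = 1.0 - 1.34 * (t / 0.0912) ** 3.94 * np.exp(-3.94 * (t / 0.0912 - 1.0))
        assert cm.eval_temporal_kernel(cm.CENTER_TEMPORAL, t) == pytest.approx(
            expected, rel=1e-12
        )

    def test_vectorized_matches_scalar(self):
        t = np.linspace(-0.1, 0.5, 37)
        vec = cm.eval_temporal_kernel(cm.SURROUND_TEMPORAL, t)
        for ti, vi in zip(t, vec):
            assert vi == pytest.approx(cm.eval_temporal_kernel(cm.SURROUND_TEMPORAL, ti))


class TestSpatialKernel:
    def test_unit_at_center_and_radius_sigma(self):
        p = cm.SpatialKernelParams(4.0)
        assert cm.eval_spatial_kernel(p, 0, 0) == 1.0
        assert cm.eval_spatial_kernel(p, 4.0, 0) == pytest.approx(np.exp(-0.5))
        assert cm.eval_spatial_kernel(p, 0, -4.0) == pytest.approx(np.exp(-0.5))

    def test_rotational_symmetry(self, rng):
        p = cm.SpatialKernelParams(3.0)
        r = rng.uniform(0, 10, 20)
        th = rng.uniform(0, 2 * np.pi, 20)
        v1 = cm.eval_spatial_kernel(p, r * np.cos(th), r * np.sin(th))
        v2 = cm.eval_spatial_kernel(p, r, np.zeros_like(r))
        np.testing.assert_allclose(v1, v2, rtol=1e-12)


def _brute_force_drive(movie, unit, n_out):
    """Triple-sum space-time convolution, independent of the separable
    fast path."""
    x, y = movie.pixel_centers()
    amp = cm.spatial_amplitude(unit.spatial.sigma)
    F = amp * np.array(
        [
            [
                cm.eval_spatial_kernel(unit.spatial, xi - unit.center[0], yj - unit.center[1])
                for xi in x
            ]
            for yj in y
        ]
    )
    dt = movie.dt
    g = np.zeros(n_out)
    for n in range(n_out):
        for k in range(movie.n_frames):
            lag = (n - k) * dt
            if lag < 0 or lag >= 0.5:
                continue
            tk = cm.eval_temporal_kernel(unit.temporal, lag)
            g[n] += np.sum(movie.values[k] * F) * tk * dt * movie.pixel_pitch**2
    return g


class TestLNResponse:
    def test_gray_movie_silent(self):
        movie = st.StimulusMovie(np.zeros((30, 20, 20)), origin=(-10, -10))
        unit = cm.LNUnit((0, 0), cm.SpatialKernelParams(4.0), cm.CENTER_TEMPORAL)
        r = cm.ln_response(movie, unit, return_drive=True)
        assert np.all(r.values == 0.0)
        assert np.all(r.drive == 0.0)

    def test_pre_rectification_linearity(self, rng):
        vals = rng.uniform(-0.5, 0.5, (25, 12, 12))
        unit = cm.LNUnit((6, 6), cm.SpatialKernelParams(3.0), cm.CENTER_TEMPORAL)
        g1 = cm.ln_response(st.StimulusMovie(vals), unit, return_drive=True).drive
        g2 = cm.ln_response(st.StimulusMovie(0.5 * vals), unit, return_drive=True).drive
        np.testing.assert_allclose(g2, 0.5 * g1, rtol=1e-10, atol=1e-14)

    def test_separable_path_matches_brute_force_convolution(self, rng):
        vals = rng.uniform(-1, 1, (20, 10, 10))
        movie = st.StimulusMovie(vals, origin=(-5, -5))
        unit = cm.LNUnit((1.0, -2.0), cm.SpatialKernelParams(2.5), cm.SURROUND_TEMPORAL)
        fast = cm.ln_response(movie, unit, return_drive=True).drive
        slow = _brute_force_drive(movie, unit, movie.n_frames)
        scale = np.abs(slow).max()
        np.testing.assert_allclose(fast / scale, slow / scale, rtol=0, atol=1e-10)

    def test_coarse_sampling_rejected(self):
        movie = st.StimulusMovie(np.zeros((5, 5, 5)), pixel_pitch=3.0)
        unit = cm.LNUnit((0, 0), cm.SpatialKernelParams(4.0), cm.CENTER_TEMPORAL)
        with pytest.raises(ValueError, match="sampling"):
            cm.ln_response(movie, unit)


class TestDetector:
    def test_silent_surround_passes_center_through(self, standard_loom):
        det = cm.make_detector((0, 0))
        # a huge threshold silences the surround unit
        det.surround_unit.rectifier = cm.Rectifier(m=1.0, theta=1e9)
        rc = cm.ln_response(standard_loom, det.center_unit)
        r = cm.detector_response(det, standard_loom)
        np.testing.assert_allclose(r.values, rc.values, rtol=1e-12)

    def test_dominant_surround_silences_detector(self, standard_loom):
        det = cm.make_detector((0, 0))
        det.surround_unit.rectifier = cm.Rectifier(m=100.0, theta=0.0)
        r = cm.detector_response(det, standard_loom)
        rs_alone = cm.ln_response(standard_loom, det.surround_unit)
        assert rs_alone.values.max() > 0  # surround genuinely active
        assert np.all(r.values[rs_alone.values > 0] <= cm.ln_response(
            standard_loom, det.center_unit).values[rs_alone.values > 0])

    def test_loom_preferred_over_other_figurals(self, circuit_config, standard_loom):
        """Centered detector: expanding dark disk beats receding,
        dimming and translating stimuli (model-simulation ordering)."""
        cfg = circuit_config
        i_center = 12  # (0, 0) on the 5x5 grid
        loom = cfg.detector_rates(standard_loom, keep_tail=True)[
            i_center, : standard_loom.n_frames
        ].sum()
        for kind in ("contract_white", "dimming", "moving_dark"):
            m = st.figural_movie(kind, (0, 0))
            other = cfg.detector_rates(m, keep_tail=True)[i_center, : m.n_frames].sum()
            assert loom > other, kind


class TestDepressingSynapse:
    def test_pure_recovery_matches_closed_form(self):
        syn = cm.DepressingSynapse(w=0.2, tau_rec=2.0, a=1.0, w_min=0.0)
        dt = syn.tau_rec / 1e4
        w = syn.w
        n = 5000
        for _ in range(n):
            w = cm.depressed_weight_step(w, 0.0, dt, syn.tau_rec, syn.a, syn.w_min)
        expected = 1.0 - (1.0 - 0.2) * np.exp(-n * dt / syn.tau_rec)
        assert w == pytest.approx(expected, rel=1e-6)

    def test_constant_rate_steady_state(self):
        syn = cm.DepressingSynapse(w=1.0, tau_rec=3.0, a=2.0, w_min=0.1)
        r = 5.0
        expected = (1 / syn.tau_rec + syn.a * syn.w_min * r) / (1 / syn.tau_rec + syn.a * r)
        assert cm.synapse_steady_state(syn, r) == pytest.approx(expected)
        w = syn.w
        B = 1 / syn.tau_rec + syn.a * r
        t_total = 8.0 / B  # several effective time constants
        dt = 1e-3
        for _ in range(int(t_total / dt)):
            w = cm.depressed_weight_step(w, r, dt, syn.tau_rec, syn.a, syn.w_min)
        assert w == pytest.approx(expected, rel=0.01)

    def test_no_depression_when_gain_zero(self):
        w = cm.depressed_weight_step(0.5, 100.0, 0.1, 2.0, a=0.0, w_min=0.0)
        w_ref = cm.depressed_weight_step(0.5, 0.0, 0.1, 2.0, a=1.0, w_min=0.0)
        assert w == pytest.approx(w_ref)

    def test_step_object_api_and_clamping(self):
        syn = cm.DepressingSynapse(w=0.05, tau_rec=1.0, a=50.0, w_min=0.0)
        out = cm.synapse_step(syn, r=100.0, dt=0.5)
        assert 0.0 <= out.w <= 1.0
        assert out.tau_rec == syn.tau_rec

    def test_exactness_under_step_halving(self, rng):
        """The exponential update is exact for frame-constant rates, so
        sub-stepping each frame leaves the trajectory unchanged."""
        rates = rng.uniform(0, 5, 50)
        w1 = w2 = 1.0
        for r in rates:
            w1 = cm.depressed_weight_step(w1, r, 0.02, 1.5, 1.0, 0.0)
            w2 = cm.depressed_weight_step(w2, r, 0.01, 1.5, 1.0, 0.0)
            w2 = cm.depressed_weight_step(w2, r, 0.01, 1.5, 1.0, 0.0)
        assert w1 == pytest.approx(w2, abs=1e-12)


class TestWidefield:
    def test_single_detector_contribution(self):
        rates = np.array([[2.0]])
        rwf, weights = cm._weight_pass(
            rates, dt=0.01, w0=np.array([0.5]), pooling=np.ones(1),
            tau_rec=180.0, a=1.0, w_min=0.0,
        )
        assert rwf[0] == pytest.approx(1.0)  # 0.5 * 2.0 with the pre-step weight
        assert weights[0, 0] == pytest.approx(0.5)

    def test_additivity_of_far_separated_looms(self, circuit_config):
        """Pre-depression pooling is linear: two simultaneous looms far
        apart drive the widefield sum like the sum of each alone."""
        cfg = circuit_config
        a = st.loom_movie((-30, -30), bounds=((-50, 50), (-50, 50)))
        b = st.loom_movie((30, 30), bounds=((-50, 50), (-50, 50)))
        both = st.StimulusMovie(a.values + b.values, origin=a.origin)
        r_a = cfg.detector_rates(a, keep_tail=True).sum(axis=0)
        r_b = cfg.detector_rates(b, keep_tail=True).sum(axis=0)
        r_ab = cfg.detector_rates(both, keep_tail=True).sum(axis=0)
        np.testing.assert_allclose(r_ab, r_a + r_b, rtol=1e-6, atol=1e-9)


class TestSimulateProtocol:
    def test_empty_protocol_relaxes_weights(self, circuit_config):
        p = st.Protocol(events=[], duration=10.0)
        sim = cm.simulate_protocol(circuit_config, p)
        assert np.all(sim.widefield == 0.0)
        assert np.all(sim.detector_rates == 0.0)
        assert np.all(sim.weights >= 0.0) and np.all(sim.weights <= 1.0)

    def test_second_loom_response_suppressed(self, circuit_config):
        p = st.repeat_loom_protocol(2, isi=2.0)
        sim = cm.simulate_protocol(circuit_config, p)
        first, second = sim.event_integrals()
        assert second < 0.25 * first

    def test_habituation_is_location_specific(self, circuit_config):
        """Depressing the synapse at one grid point leaves the weights
        of silent detectors untouched."""
        p = st.repeat_loom_protocol(3, isi=2.0, location=(0.0, 0.0))
        sim = cm.simulate_protocol(circuit_config, p)
        centers = sim.detector_centers
        i_stim = np.flatnonzero((centers == (0.0, 0.0)).all(axis=1))[0]
        final = sim.weights[:, -1]
        assert final[i_stim] < 0.1
        others = np.delete(final, i_stim)
        assert np.all(others > 1.0 - 1e-9)

    def test_position_invariance_and_latency(self, circuit_config):
        """Fresh looms at the nine interior grid points give equal
        integrated responses (CV < 10%) with identical onset frames."""
        ints, onsets = [], []
        for c in circuit_config.detector_centers():
            if abs(c[0]) > 15 or abs(c[1]) > 15:
                continue
            p = st.repeat_loom_protocol(1, isi=1.0, location=tuple(c))
            sim = cm.simulate_protocol(circuit_config, p)
            ints.append(sim.event_integrals()[0])
            wf = sim.widefield
            onsets.append(int(np.flatnonzero(wf > 0.05 * wf.max())[0]))
        ints = np.asarray(ints)
        assert ints.std() / ints.mean() < 0.10
        assert max(onsets) - min(onsets) <= 1

    def test_recovery_fractions_track_isi(self, circuit_config):
        """Longer gaps allow deeper recovery (monotone from the second
        interval on; the first starts from a shallower depletion), and
        two minutes is not enough to recover half the naive response."""
        sim = cm.simulate_protocol(circuit_config, st.recovery_protocol())
        ints = sim.event_integrals()
        frac = ints / ints[0]
        assert np.all(np.diff(frac[2:]) > 0)
        assert frac[-1] < 0.5  # ISI 121 s with tau_rec = 180 s

    def test_off_grid_event_warns(self, circuit_config):
        p = st.Protocol(
            events=[st.TrialEvent("loom_dark", (100.0, 0.0), 0.0, 0.75)],
            duration=2.0,
        )
        with pytest.warns(UserWarning, match="outside the detector grid"):
            cm.simulate_protocol(circuit_config, p)
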
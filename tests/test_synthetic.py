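"""Generator correctness: stimuli, kernels, LN simulation, spiking,
templates, and group presets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strfdev import intrinsic, receptive_field as rf, synthetic as syn


class TestGratingStimulus:
    def test_contrasts_bounded(self):
        m = syn.make_grating_stimulus(45.0, tf_hz=6.0, duration_s=2.0)
        assert np.all(np.abs(m.contrast) <= 1.0 + 1e-12)

    def test_opposite_directions_are_temporal_mirrors(self):
        a = syn.make_grating_stimulus(0.0, duration_s=1.0)
        b = syn.make_grating_stimulus(180.0, duration_s=1.0)
        # cos(2*pi*(sf x - tf t)) vs cos(2*pi*(-sf x - tf t)): direction and
        # its opposite differ only in the sign of the temporal term
        x = a.space_axis_deg
        t = np.arange(a.n_frames) * a.frame_ms / 1000.0
        expected_b = np.cos(2 * np.pi * (-0.08 * x[:, None] - 4.0 * t[None, :]))
        np.testing.assert_allclose(b.contrast, expected_b, atol=1e-12)
        expected_a = np.cos(2 * np.pi * (0.08 * x[:, None] - 4.0 * t[None, :]))
        np.testing.assert_allclose(a.contrast, expected_a, atol=1e-12)

    def test_spatial_period_spans_four_bars(self):
        # sf = 0.08 cpd -> period 12.5 deg =~ 4 bars of 3.1 deg
        m = syn.make_grating_stimulus(0.0, duration_s=0.1, bar_width_deg=3.1)
        frame = m.contrast[:, 0]
        # autocorrelation peak at ~4 bars lag
        period_bars = 12.5 / 3.1
        assert frame[0] == pytest.approx(frame[4], abs=0.15)
        assert 3 < period_bars < 5

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            syn.make_grating_stimulus(0.0, duration_s=-1.0)
        with pytest.raises(ValueError):
            syn.make_grating_stimulus(0.0, n_positions=0)


class TestSparseNoise:
    def test_frame_count(self):
        m = syn.make_sparse_noise(duration_s=10.0, frame_ms=100.0)
        assert m.n_frames == 100

    def test_deterministic_in_seed(self):
        a = syn.make_sparse_noise(duration_s=5.0, seed=3)
        b = syn.make_sparse_noise(duration_s=5.0, seed=3)
        np.testing.assert_array_equal(a.contrast, b.contrast)

    def test_contrast_frequencies(self):
        m = syn.make_sparse_noise(n_positions=1, duration_s=10000.0, seed=0)
        vals, counts = np.unique(m.contrast, return_counts=True)
        freqs = dict(zip(vals, counts / m.contrast.size))
        assert freqs[-1.0] == pytest.approx(0.10, abs=0.01)
        assert freqs[1.0] == pytest.approx(0.10, abs=0.01)
        assert freqs[0.0] == pytest.approx(0.80, abs=0.01)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            syn.make_sparse_noise(p_black=0.7, p_white=0.7)
        with pytest.raises(ValueError):
            syn.make_sparse_noise(p_black=-0.1)


class TestGroundTruthKernel:
    def test_zero_tilt_kernel_is_unselective(self):
        k = syn.make_ground_truth_kernel(5.0, 60.0, tilt_cyc_per_ms=0.0)
        pred = rf.predict_dsi_fft(rf.kernel_to_strf(k))
        assert pred.dsi_pr == pytest.approx(0.0, abs=1e-9)

    def test_zero_amplitude_kernel(self):
        k = syn.make_ground_truth_kernel(5.0, 60.0, amplitude=0.0)
        assert np.all(k.weights == 0)

    def test_predicted_dsi_increases_with_tilt(self):
        tilts = [0.0002, 0.0004, 0.0006, 0.0008, 0.0012]
        dsis = [rf.predict_dsi_fft(rf.kernel_to_strf(
            syn.make_ground_truth_kernel(5.0, 70.0, tilt_cyc_per_ms=t))).dsi_pr
            for t in tilts]
        assert np.all(np.diff(dsis) > 0)

    def test_negative_lag_axis_rejected(self):
        with pytest.raises(ValueError):
            syn.make_ground_truth_kernel(5.0, 60.0,
                                         lag_axis_ms=np.arange(-50.0, 200.0))


class TestSimulateVm:
    def test_zero_kernel_gives_baseline(self):
        k = syn.make_ground_truth_kernel(5.0, 60.0, amplitude=0.0)
        stim = syn.make_sparse_noise(duration_s=5.0, seed=1)
        vm = syn.simulate_vm(stim, k, noise_sd=0.0, baseline_mV=-70.0)
        np.testing.assert_allclose(vm.samples, -70.0)

    def test_linearity_in_contrast(self):
        from dataclasses import replace
        k = syn.make_ground_truth_kernel(5.0, 60.0, tilt_cyc_per_ms=0.0005)
        stim = syn.make_sparse_noise(duration_s=5.0, seed=1)
        stim2 = replace(stim, contrast=2.0 * stim.contrast)
        v1 = syn.simulate_vm(stim, k, noise_sd=0.0, baseline_mV=-70.0)
        v2 = syn.simulate_vm(stim2, k, noise_sd=0.0, baseline_mV=-70.0)
        np.testing.assert_allclose(v2.samples + 70.0,
                                   2.0 * (v1.samples + 70.0), atol=1e-9)

    def test_delta_kernel_shifts_stimulus(self):
        # a unit weight at (x0, tau0) makes Vm(t) = baseline + c(x0, t-tau0)
        n_pos, tau0, x0 = 6, 40, 2
        w = np.zeros((n_pos, 100))
        w[x0, tau0] = 1.0
        k = syn.KernelSTRF(weights=w, space_axis_deg=np.arange(n_pos) * 3.1,
                           lag_axis_ms=np.arange(100.0))
        stim = syn.make_sparse_noise(n_positions=n_pos, duration_s=5.0, seed=4)
        vm = syn.simulate_vm(stim, k, noise_sd=0.0, baseline_mV=-70.0)
        c = syn.upsample_stimulus(stim, 1.0)
        expected = -70.0 + np.concatenate([np.zeros(tau0), c[x0, :-tau0]])
        np.testing.assert_allclose(vm.samples, expected, atol=1e-9)

    def test_matches_triple_loop_convolution(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(3, 8))
        k = syn.KernelSTRF(weights=w, space_axis_deg=np.arange(3.0),
                           lag_axis_ms=np.arange(8.0))
        stim = syn.make_sparse_noise(n_positions=3, duration_s=0.5,
                                     frame_ms=10.0, seed=5)
        vm = syn.simulate_vm(stim, k, noise_sd=0.0, baseline_mV=0.0)
        c = syn.upsample_stimulus(stim, 1.0)
        n_t = c.shape[1]
        oracle = np.zeros(n_t)
        for t in range(n_t):
            for x in range(3):
                for tau in range(8):
                    if t - tau >= 0:
                        oracle[t] += w[x, tau] * c[x, t - tau]
        np.testing.assert_allclose(vm.samples, oracle, atol=1e-10)


class TestSimulateSpikes:
    def test_subthreshold_vm_gives_empty_train(self):
        p = syn.VFParams(b=1.0, vth_mV=0.0, alpha=2.0)
        spk = syn.simulate_spikes(np.full(1000, -5.0), p, dt_ms=1.0, seed=0)
        assert len(spk) == 0

    def test_isis_respect_refractory(self):
        p = syn.VFParams(b=1.0, vth_mV=0.0, alpha=1.0)
        spk = syn.simulate_spikes(np.full(50000, 80.0), p, refractory_ms=5.0,
                                  dt_ms=1.0, seed=1, max_rate_hz=150.0)
        assert len(spk) > 100
        assert np.all(np.diff(spk.times_ms) >= 5.0)

    def test_constant_rate_poisson_count(self):
        # 20 sp/s for 100 s, no refractory: count within 3 sigma of 2000
        p = syn.VFParams(b=1.0, vth_mV=0.0, alpha=1.0)
        spk = syn.simulate_spikes(np.full(100000, 20.0), p, refractory_ms=0.0,
                                  dt_ms=1.0, seed=2)
        assert abs(len(spk) - 2000) < 3 * np.sqrt(2000)

    def test_rate_dt_overflow_rejected(self):
        p = syn.VFParams(b=1.0, vth_mV=0.0, alpha=1.0)
        with pytest.raises(ValueError):
            syn.simulate_spikes(np.full(10, 2000.0), p, dt_ms=1.0, seed=0)


class TestSpikeInjection:
    def test_empty_train_leaves_trace_unchanged(self):
        vm = syn.VmTrace(samples=np.full(100, -70.0), dt_ms=1.0)
        out = syn.inject_spike_waveforms(vm, syn.SpikeTrain(times_ms=np.array([])),
                                         syn.SpikeShape(-25.0, 162.1, 1.6))
        np.testing.assert_array_equal(out.samples, vm.samples)

    def test_template_metrics_recover_settings(self):
        shape = syn.SpikeShape(kink_mV=-30.2, max_dvdt_mV_per_ms=264.4,
                               fwhm_ms=1.0)
        dt = 0.1
        hold = shape.kink_mV - shape.foot_mV
        base = syn.VmTrace(samples=np.full(2000, hold), dt_ms=dt)
        vm = syn.inject_spike_waveforms(
            base, syn.SpikeTrain(times_ms=np.array([100.0])), shape)
        w, mean_w = intrinsic.extract_spike_waveforms(vm.samples, [102.0], dt)
        assert abs(intrinsic.spike_kink(mean_w, dt) - shape.kink_mV) < 1.0
        assert (abs(intrinsic.max_dvdt(mean_w, dt) - shape.max_dvdt_mV_per_ms)
                / shape.max_dvdt_mV_per_ms) < 0.05
        assert abs(intrinsic.spike_fwhm(mean_w, dt) - shape.fwhm_ms) < 0.05

    def test_nonoverlapping_spikes_are_shift_copies(self):
        shape = syn.SpikeShape(-25.0, 200.0, 1.2)
        base = syn.VmTrace(samples=np.full(400, -35.0), dt_ms=1.0)
        vm = syn.inject_spike_waveforms(
            base, syn.SpikeTrain(times_ms=np.array([100.0, 150.0])), shape)
        np.testing.assert_allclose(vm.samples[100:130], vm.samples[150:180])

    def test_spike_outside_trace_rejected(self):
        vm = syn.VmTrace(samples=np.full(100, -70.0), dt_ms=1.0)
        with pytest.raises(ValueError):
            syn.inject_spike_waveforms(
                vm, syn.SpikeTrain(times_ms=np.array([500.0])),
                syn.SpikeShape(-25.0, 162.1, 1.6))


class TestPopulationPresets:
    def test_same_seed_identical_population(self):
        a = syn.make_cell_population("naive", 4, seed=5)
        b = syn.make_cell_population("naive", 4, seed=5)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.kernel.weights, cb.kernel.weights)
            assert ca.vf == cb.vf and ca.spike_shape == cb.spike_shape

    def test_empty_population(self):
        assert syn.make_cell_population("experienced", 0, seed=1) == []

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            syn.make_cell_population("adolescent", 5, seed=0)

    def test_experienced_kink_mean_matches_preset(self):
        cells = syn.make_cell_population("experienced", 200, seed=42)
        mean_kink = np.mean([c.spike_shape.kink_mV for c in cells])
        assert abs(mean_kink - (-30.2)) < 1.0

    def test_group_contrasts(self):
        nai = syn.make_cell_population("naive", 50, seed=1)
        exp = syn.make_cell_population("experienced", 50, seed=2)
        mean = lambda cells, f: np.mean([f(c) for c in cells])
        assert mean(exp, lambda c: abs(c.kernel.tilt_cyc_per_ms)) > \
            mean(nai, lambda c: abs(c.kernel.tilt_cyc_per_ms))
        assert mean(exp, lambda c: c.spike_shape.max_dvdt_mV_per_ms) > \
            mean(nai, lambda c: c.spike_shape.max_dvdt_mV_per_ms)
        assert mean(exp, lambda c: c.spike_shape.fwhm_ms) < \
            mean(nai, lambda c: c.spike_shape.fwhm_ms)
        assert mean(exp, lambda c: c.kernel.t_center_ms) < \
            mean(nai, lambda c: c.kernel.t_center_ms)
        assert mean(exp, lambda c: c.vf.b) > mean(nai, lambda c: c.vf.b)
        assert mean(exp, lambda c: c.vf.vth_mV) < mean(nai, lambda c: c.vf.vth_mV)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_noise_generator_is_pure_function_of_seed(seed):
    a = syn.make_sparse_noise(duration_s=1.0, seed=seed)
    b = syn.make_sparse_noise(duration_s=1.0, seed=seed)
    np.testing.assert_array_equal(a.contrast, b.contrast)
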
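"""Reverse correlation, subunit extraction, ellipse geometry, spectral DSI."""

import numpy as np
import pytest
from scipy import ndimage

from strfdev import receptive_field as rf, synthetic as syn


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestReverseCorrelate:
    def test_constant_vm_gives_zero_map(self):
        stim = syn.make_sparse_noise(duration_s=20.0, seed=1)
        vm = syn.VmTrace(samples=np.full(20000, -70.0), dt_ms=1.0)
        strf = rf.reverse_correlate(vm, stim)
        np.testing.assert_allclose(strf.corr, 0.0, atol=1e-12)

    def test_delta_kernel_peak_location(self):
        n_pos, x0, tau0 = 8, 3, 150
        w = np.zeros((n_pos, 400))
        w[x0, tau0] = 1.0
        k = syn.KernelSTRF(weights=w, space_axis_deg=np.arange(n_pos) * 3.1,
                           lag_axis_ms=np.arange(400.0))
        stim = syn.make_sparse_noise(n_positions=n_pos, duration_s=300.0, seed=2)
        vm = syn.simulate_vm(stim, k, noise_sd=0.0, baseline_mV=-70.0)
        strf = rf.reverse_correlate(vm, stim)
        peak = np.unravel_index(np.argmax(strf.corr), strf.corr.shape)
        assert peak[0] == x0
        assert abs(strf.lag_axis_ms[peak[1]] - tau0) <= 100.0  # one frame

    def test_dc_invariance_when_normalized(self):
        stim = syn.make_sparse_noise(duration_s=30.0, seed=3)
        k = syn.make_ground_truth_kernel(6.0, 50.0, tilt_cyc_per_ms=0.0005,
                                         amplitude=0.01)
        vm = syn.simulate_vm(stim, k, noise_sd=0.0, baseline_mV=-70.0)
        shifted = syn.VmTrace(samples=vm.samples + 13.0, dt_ms=1.0)
        a = rf.reverse_correlate(vm, stim)
        b = rf.reverse_correlate(shifted, stim)
        np.testing.assert_allclose(a.corr, b.corr, atol=1e-12)

    def test_estimate_matches_blurred_kernel(self, experienced_cell,
                                             experienced_noise_recording):
        stim, vm, _, _ = experienced_noise_recording
        strf = rf.reverse_correlate(vm, stim)
        blur = ndimage.uniform_filter1d(experienced_cell.kernel.weights,
                                        size=100, axis=1, mode="constant")
        blur = blur[:, : 400 // 10 * 10].reshape(blur.shape[0], -1, 10).mean(axis=2)
        n = min(strf.corr.shape[1], blur.shape[1])
        r = np.corrcoef(strf.corr[:, :n].ravel(), blur[:, :n].ravel())[0, 1]
        assert r > 0.8

    def test_consistency_improves_with_duration(self, experienced_cell):
        from conftest import simulate_recording
        blur = ndimage.uniform_filter1d(experienced_cell.kernel.weights,
                                        size=100, axis=1, mode="constant")
        blur = blur[:, : 400 // 10 * 10].reshape(blur.shape[0], -1, 10).mean(axis=2)
        rs = []
        for dur in (60.0, 300.0):
            stim, vm, _, _ = simulate_recording(experienced_cell, dur, seed=77)
            strf = rf.reverse_correlate(vm, stim)
            n = min(strf.corr.shape[1], blur.shape[1])
            rs.append(np.corrcoef(strf.corr[:, :n].ravel(),
                                  blur[:, :n].ravel())[0, 1])
        assert rs[1] > rs[0]


class TestExtractSubunits:
    def test_small_cluster_rejected(self):
        img = np.zeros((30, 40))
        img[5:7, 5:10] = 1.0  # 10-pixel cluster
        strf = rf.STRFMap(corr=img, space_axis_deg=np.arange(30.0),
                          lag_axis_ms=np.arange(40.0))
        assert rf.extract_subunits(strf) == []

    def test_on_and_off_blobs(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0, 0.01, (40, 50))
        img[5:11, 5:10] = 1.0    # 30-pixel positive blob
        img[25:31, 30:35] = -1.0  # 30-pixel negative blob
        strf = rf.STRFMap(corr=img, space_axis_deg=np.arange(40.0),
                          lag_axis_ms=np.arange(50.0))
        subs = rf.extract_subunits(strf)
        polarities = sorted(s.polarity for s in subs)
        assert polarities == ["OFF", "ON"]

    def test_gabor_strf_has_alternating_subunits(self, experienced_cell,
                                                 experienced_noise_recording):
        stim, vm, _, _ = experienced_noise_recording
        strf = rf.reverse_correlate(vm, stim)
        subs = [rf.fit_ellipse(c, strf=strf)
                for c in rf.extract_subunits(strf)]
        assert len(subs) >= 2
        assert {s.polarity for s in subs} == {"ON", "OFF"}
        # ON and OFF centroids alternate along the space axis
        order = sorted(subs, key=lambda s: s.centroid_space_px)
        assert any(a.polarity != b.polarity
                   for a, b in zip(order[:-1], order[1:]))


class TestFitEllipse:
    def test_filled_circle(self):
        mask = _disk_mask((40, 40), (20, 20), 10)
        ell = rf.fit_ellipse(rf.PixelCluster("ON", mask))
        assert ell.eccentricity < 0.1
        assert ell.major_axis_px == pytest.approx(ell.minor_axis_px, rel=0.05)

    def test_axis_aligned_rectangle(self):
        mask = np.zeros((60, 30), dtype=bool)
        mask[10:50, 10:20] = True  # 40 px along space axis, 10 px along lag
        ell = rf.fit_ellipse(rf.PixelCluster("ON", mask))
        assert ell.orientation_deg == pytest.approx(0.0, abs=1.0)
        assert ell.major_axis_px / ell.minor_axis_px == pytest.approx(4.0,
                                                                      rel=0.05)

    def test_rotation_covariance(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[30:50, 36:44] = True
        rot = ndimage.rotate(mask.astype(float), 30.0, reshape=False,
                             order=0) > 0.5
        e0 = rf.fit_ellipse(rf.PixelCluster("ON", mask))
        e1 = rf.fit_ellipse(rf.PixelCluster("ON", rot))
        assert abs(e1.orientation_deg - 30.0) < 6.0
        assert e1.eccentricity == pytest.approx(e0.eccentricity, abs=0.05)
        assert e1.area_px == pytest.approx(e0.area_px, rel=0.10)

    def test_degenerate_line_cluster(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:27, 9] = True
        ell = rf.fit_ellipse(rf.PixelCluster("OFF", mask))
        assert ell.minor_axis_px >= 1.0
        assert 0.0 <= ell.eccentricity < 1.0


class TestShapeParameters:
    def test_axis_aligned_extents(self):
        # centered at lag 150 ms, semi-axes 20 deg (space) x 50 ms (time):
        # the lag axis is 10 ms/px so the time semi-axis is 5 px
        ell = rf.SubunitShape("ON", 100, 10.0, 14.5, 0.9, 2 * 20.0, 2 * 5.0,
                              90.0, 100.0)
        space_axis = np.arange(24) * 1.0
        lag_axis = (np.arange(40) + 0.5) * 10.0
        sp = rf.shape_parameters(ell, space_axis, lag_axis)
        # orientation 90 deg: major axis along the lag axis
        assert sp.temporal_extent_ms == pytest.approx(400.0)
        assert sp.min_latency_ms == pytest.approx(150.0 - 200.0)
        assert sp.max_latency_ms == pytest.approx(150.0 + 200.0)
        assert sp.spatial_extent_deg == pytest.approx(10.0)

    def test_rotating_90_swaps_extents(self):
        space_axis = np.arange(40) * 1.0
        lag_axis = (np.arange(40) + 0.5) * 1.0
        a = rf.shape_parameters(
            rf.SubunitShape("ON", 50, 20.0, 20.0, 0.8, 16.0, 6.0, 0.0, 50.0),
            space_axis, lag_axis)
        b = rf.shape_parameters(
            rf.SubunitShape("ON", 50, 20.0, 20.0, 0.8, 16.0, 6.0, 90.0, 50.0),
            space_axis, lag_axis)
        assert a.spatial_extent_deg == pytest.approx(b.temporal_extent_ms)
        assert a.temporal_extent_ms == pytest.approx(b.spatial_extent_deg)

    def test_tilted_extents_match_boundary_sampling(self):
        rng = np.random.default_rng(1)
        space_axis = np.arange(50) * 1.0
        lag_axis = (np.arange(50) + 0.5) * 1.0
        for _ in range(20):
            a, b = rng.uniform(5, 20), rng.uniform(2, 8)
            theta = rng.uniform(0, 90)
            ell = rf.SubunitShape("ON", 100, 20.0, 25.0, 0.5, 2 * a, 2 * b,
                                  theta, 100.0)
            sp = rf.shape_parameters(ell, space_axis, lag_axis)
            t = np.linspace(0, 2 * np.pi, 100_000)
            c, s = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
            xs = 20.0 + a * np.cos(t) * c - b * np.sin(t) * s
            ys = 25.5 + a * np.cos(t) * s + b * np.sin(t) * c
            assert sp.spatial_extent_deg == pytest.approx(xs.max() - xs.min(),
                                                          abs=1.0)
            assert sp.temporal_extent_ms == pytest.approx(ys.max() - ys.min(),
                                                          abs=1.0)
            assert sp.min_latency_ms == pytest.approx(ys.min(), abs=1.0)
            assert sp.max_latency_ms == pytest.approx(ys.max(), abs=1.0)


class TestCellAverage:
    def test_single_subunit_identity(self):
        ell = rf.SubunitShape("ON", 30, 1.0, 2.0, 0.5, 8.0, 4.0, 20.0, 30.0,
                              10.0, 50.0, 100.0, 150.0)
        avg = rf.cell_average([ell])
        assert avg == ell.parameters()

    def test_mean_of_two(self):
        a = rf.SubunitShape("ON", 30, 1.0, 2.0, 0.5, 8.0, 4.0, 20.0, 30.0,
                            10.0, 50.0, 50.0, 150.0)
        b = rf.SubunitShape("OFF", 30, 1.0, 2.0, 0.7, 8.0, 4.0, 20.0, 30.0,
                            10.0, 50.0, 150.0, 150.0)
        avg = rf.cell_average([a, b])
        assert avg["min_latency_ms"] == 100.0
        assert avg["eccentricity"] == pytest.approx(0.6)

    def test_no_subunits(self):
        assert rf.cell_average([]) is None


class TestPeakCorrelationCheck:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        classes = {k: rng.normal(0.3, 0.05, 20) for k in
                   ("Naive_ON", "Naive_OFF", "Exp_ON", "Exp_OFF")}
        assert rf.peak_correlation_check(classes) > 0.05

    def test_shifted_class_significant(self):
        rng = np.random.default_rng(1)
        classes = {k: rng.normal(0.3, 0.05, 20) for k in
                   ("Naive_ON", "Naive_OFF", "Exp_ON")}
        classes["Exp_OFF"] = rng.normal(0.8, 0.05, 20)
        assert rf.peak_correlation_check(classes) < 0.001

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            rf.peak_correlation_check({"A": [1.0], "B": [1.0, 2.0]})


class TestPredictDsiFFT:
    def test_separable_kernel_unselective(self):
        k = syn.make_ground_truth_kernel(5.0, 60.0, tilt_cyc_per_ms=0.0)
        assert rf.predict_dsi_fft(rf.kernel_to_strf(k)).dsi_pr == \
            pytest.approx(0.0, abs=1e-9)

    def test_drifting_kernel_fully_selective(self):
        # broad drifting wave under a smooth window: energy concentrates in
        # one temporal-frequency sign
        x = (np.arange(48) - 23.5)[:, None] * 1.55
        t = np.arange(0.0, 400.0)[None, :]
        w = np.cos(2 * np.pi * (0.08 * x + 0.004 * t))
        w = w * np.outer(np.hanning(48), np.hanning(400))
        k = syn.KernelSTRF(weights=w, space_axis_deg=x.ravel(),
                           lag_axis_ms=t.ravel())
        assert rf.predict_dsi_fft(rf.kernel_to_strf(k)).dsi_pr > 0.9

    def test_polarity_symmetry(self):
        from dataclasses import replace
        cell = syn.make_synthetic_cell("experienced", seed=5)
        strf = rf.kernel_to_strf(cell.kernel)
        flipped = replace(strf, corr=-strf.corr)
        a = rf.predict_dsi_fft(strf)
        b = rf.predict_dsi_fft(flipped)
        assert a.dsi_pr == pytest.approx(b.dsi_pr, abs=1e-12)
        # negating the kernel swaps ON and OFF subunits with same geometry
        subs_a = rf.analyze_subunits(strf, min_pixels=10)
        subs_b = rf.analyze_subunits(flipped, min_pixels=10)
        on_a = sorted(s.centroid_space_px for s in subs_a if s.polarity == "ON")
        off_b = sorted(s.centroid_space_px for s in subs_b if s.polarity == "OFF")
        np.testing.assert_allclose(on_a, off_b)

    def test_zero_map_rejected(self):
        strf = rf.STRFMap(corr=np.zeros((10, 10)),
                          space_axis_deg=np.arange(10.0),
                          lag_axis_ms=np.arange(10.0))
        with pytest.raises(ValueError):
            rf.predict_dsi_fft(strf)


def test_shape_parameters_correlate_with_vm_dsi():
    """Across synthetic cells, eccentricity correlates positively and minimum
    latency negatively with the kernel's predicted direction selectivity."""
    ecc, minlat, dsis = [], [], []
    for i in range(24):
        g = "naive" if i % 2 else "experienced"
        cell = syn.make_synthetic_cell(g, seed=3000 + i)
        strf = rf.kernel_to_strf(cell.kernel)
        subs = rf.analyze_subunits(strf)
        avg = rf.cell_average(subs)
        if avg is None:
            continue
        ecc.append(avg["eccentricity"])
        minlat.append(avg["min_latency_ms"])
        dsis.append(rf.predict_dsi_fft(strf).dsi_pr)
    from scipy import stats
    assert stats.pearsonr(ecc, dsis).statistic > 0
    assert stats.pearsonr(minlat, dsis).statistic < 0
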
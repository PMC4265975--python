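"""Thermometry: PRFS arithmetic, drift correction, T2 mapping, projections."""

import numpy as np
import pytest

from sonasim import phantoms
from sonasim import scanner as sc
from sonasim import thermometry as th
from sonasim.bioheat import TemperatureField
from sonasim.grids import Grid3D


def make_params(**kw):
    defaults = dict(fov_mm=64, matrix=64, pixel_mm=1.0, slice_thickness_mm=5.0,
                    te_ms=20.0, tr_ms=30.0, dynamic_time_s=0.59, b0_t=3.0)
    defaults.update(kw)
    return sc.SequenceParams(**defaults)


@pytest.fixture()
def block():
    return phantoms.polymer_block_phantom(extent_mm=(80, 80, 40),
                                          spacing_mm=2.0)


@pytest.fixture()
def stack():
    return sc.StackGeometry(center_mm=(0.0, 0.0, 0.0))


def aligned_hotspot(peak_c, sigma_mm=8.0, baseline_c=20.0):
    """Temperature grid whose nodes coincide with the 64x64 1-mm pixel
    centres of make_params(), so sampling is exact."""
    grid = Grid3D(origin_mm=(-31.5, -31.5, -5.0), spacing_mm=1.0,
                  shape=(64, 64, 11))
    xx, yy, zz = np.meshgrid(*grid.axes_mm(), indexing="ij")
    dT = peak_c * np.exp(-(xx ** 2 + yy ** 2 + zz ** 2) / (2 * sigma_mm ** 2))
    return TemperatureField(grid, baseline_c + dT, 0.0), dT[:, :, 5]


class TestPrfs:
    def test_identical_frames_give_zero(self, block, stack):
        params = make_params()
        f = sc.synthesize_frame(block, None, stack, params)
        tmap = th.prfs_delta_t(f, f)
        np.testing.assert_array_equal(tmap.delta_t_c[tmap.valid], 0.0)

    def test_closed_form_scaling(self):
        """Delta-phi = -1.605 rad at TE = 20 ms, 3 T maps to +10.0 degC."""
        cfg = th.ThermometryConfig(te_ms=20.0, b0_t=3.0)
        assert -1.605 / cfg.rad_per_degc() == pytest.approx(10.0, abs=0.01)

    @pytest.mark.parametrize("peak", [10.0, 15.0, -15.0])
    def test_round_trip_recovers_hotspot(self, block, stack, peak):
        """Synthesize -> measure recovers a Gaussian hot spot with max
        error < 0.1 degC, noiseless, for |dT| <= 15 degC."""
        params = make_params()
        temp, truth = aligned_hotspot(peak)
        ref = sc.synthesize_frame(block, None, stack, params)
        frm = sc.synthesize_frame(block, temp, stack, params)
        tmap = th.prfs_delta_t(frm, ref)
        assert np.abs(tmap.delta_t_c - truth).max() < 0.1

    def test_te_mismatch_rejected(self, block, stack):
        a = sc.synthesize_frame(block, None, stack, make_params(te_ms=20.0))
        b = sc.synthesize_frame(block, None, stack, make_params(te_ms=16.0))
        with pytest.raises(th.ThermometryError, match="TE"):
            th.prfs_delta_t(a, b)

    def test_low_magnitude_pixels_masked_invalid(self, stack):
        phantom = phantoms.polymer_block_phantom(extent_mm=(30, 30, 20),
                                                 spacing_mm=2.0)
        params = make_params()  # 64-mm FOV > 30-mm phantom: air around
        f = sc.synthesize_frame(phantom, None, stack, params)
        tmap = th.prfs_delta_t(f, f)
        assert not tmap.valid[0, 0]       # outside the phantom
        assert tmap.valid[32, 32]         # inside


class TestDriftCorrection:
    def roi(self):
        roi = np.zeros((64, 64), dtype=bool)
        roi[4:16, 4:16] = True
        return roi

    def test_uniform_drift_removed_exactly(self, block, stack):
        params = make_params()
        ref = sc.synthesize_frame(block, None, stack, params)
        drifted = sc.synthesize_frame(block, None, stack, params,
                                      drift_rad=0.5 * 0.1605)  # ~0.5 degC
        tmap = th.prfs_delta_t(drifted, ref)
        corrected = th.drift_correct(tmap, self.roi())
        use = self.roi() & corrected.valid
        assert abs(corrected.delta_t_c[use].mean()) < 1e-12

    def test_zero_drift_map_unchanged(self, block, stack):
        params = make_params()
        f = sc.synthesize_frame(block, None, stack, params)
        tmap = th.prfs_delta_t(f, f)
        corrected = th.drift_correct(tmap, self.roi())
        np.testing.assert_allclose(corrected.delta_t_c, tmap.delta_t_c,
                                   atol=1e-12)

    def test_hotspot_outside_roi_unperturbed(self, block, stack):
        """Drift + disjoint hot spot: correction removes the drift while
        moving the hot-spot peak by < 0.05 degC."""
        params = make_params()
        temp, truth = aligned_hotspot(10.0)
        ref = sc.synthesize_frame(block, None, stack, params)
        frm = sc.synthesize_frame(block, temp, stack, params, drift_rad=0.08)
        corrected = th.drift_correct(th.prfs_delta_t(frm, ref), self.roi())
        peak = corrected.delta_t_c[32, 32]
        assert abs(peak - truth[32, 32]) < 0.05

    def test_idempotent(self, block, stack):
        params = make_params()
        temp, _ = aligned_hotspot(5.0)
        ref = sc.synthesize_frame(block, None, stack, params)
        frm = sc.synthesize_frame(block, temp, stack, params, drift_rad=0.3)
        once = th.drift_correct(th.prfs_delta_t(frm, ref), self.roi())
        twice = th.drift_correct(once, self.roi())
        np.testing.assert_allclose(twice.delta_t_c, once.delta_t_c,
                                   atol=1e-12)

    def test_empty_roi_rejected(self, block, stack):
        params = make_params()
        f = sc.synthesize_frame(block, None, stack, params)
        tmap = th.prfs_delta_t(f, f)
        with pytest.raises(th.ThermometryError):
            th.drift_correct(tmap, np.zeros((64, 64), dtype=bool))


class TestT2:
    def test_log_ratio_closed_form(self):
        s1 = np.full((4, 4), np.e)
        s2 = np.ones((4, 4))
        t2, valid = th.t2_map(s1, s2, 40.0, 180.0)
        assert valid.all()
        np.testing.assert_allclose(t2, 140.0)  # (180-40)/ln(e)

    def test_degenerate_pixels_masked_not_fatal(self):
        s1 = np.array([[1.0, 0.5, 0.0]])
        s2 = np.array([[1.0, 0.7, 0.2]])
        t2, valid = th.t2_map(s1, s2, 40.0, 180.0)
        assert not valid.any()  # S1 <= S2 or S1 <= 0 everywhere

    def test_round_trip_recovers_marrow_t2_within_1pct(self, stack):
        femur = phantoms.femur_phantom()
        params = make_params(te_ms=40.0, tr_ms=2400.0, te2_ms=180.0,
                             dynamic_time_s=9.7, matrix=40, fov_mm=60,
                             pixel_mm=1.5)
        frame = sc.synthesize_frame(femur, None, stack, params)
        t2, valid = th.t2_map_from_frame(frame)
        # marrow core has T2 = 100 ms
        assert valid[20, 20]
        assert t2[20, 20] == pytest.approx(100.0, rel=0.01)

    def test_t2_to_temp_scaling(self):
        t2 = np.full((3, 3), 250.0)
        ref = np.full((3, 3), 150.0)
        tmap = th.t2_to_temp(t2, ref, slope_ms_per_c=20.0)
        np.testing.assert_allclose(tmap.delta_t_c, 5.0)  # 100 ms / 20 ms/degC
        zero = th.t2_to_temp(ref, ref, 20.0)
        np.testing.assert_allclose(zero.delta_t_c, 0.0)

    def test_injected_slope_recovered_at_snr_50(self, stack):
        """Simulated marrow heat-up at SNR 50: regressing two-echo T2
        against the known temperature recovers the injected 20 ms/degC
        within 5%."""
        femur = phantoms.femur_phantom()
        params = make_params(te_ms=40.0, tr_ms=2400.0, te2_ms=180.0,
                             dynamic_time_s=9.7, matrix=40, fov_mm=60,
                             pixel_mm=1.5)
        # SNR 50 on the first-echo marrow signal
        s1 = np.exp(-40.0 / 100.0)
        noise_sd = s1 / 50.0
        rng = np.random.default_rng(7)
        temps = np.linspace(0.0, 5.0, 12)
        grid = Grid3D(origin_mm=(-30.0, -30.0, -9.0), spacing_mm=1.5,
                      shape=(41, 41, 13))
        t2_center = []
        for dT in temps:
            temp = TemperatureField(grid, np.full(grid.shape, 20.0 + dT), 0.0)
            frame = sc.synthesize_frame(femur, temp, stack, params,
                                        noise_sd=noise_sd, rng=rng)
            t2, valid = th.t2_map_from_frame(frame)
            core = t2[18:23, 18:23]
            t2_center.append(np.nanmean(core))
        slope = np.polyfit(temps, t2_center, 1)[0]
        assert slope == pytest.approx(20.0, rel=0.05)


class TestMaxProjection:
    def make_map(self, arr, valid=None, dynamic=0, time_s=0.0):
        v = np.ones_like(arr, dtype=bool) if valid is None else valid
        return th.TemperatureMap(arr, v, dynamic=dynamic, time_s=time_s)

    def test_single_map_is_identity(self):
        m = self.make_map(np.arange(9.0).reshape(3, 3))
        out = th.max_projection([m])
        np.testing.assert_array_equal(out.delta_t_c, m.delta_t_c)

    def test_disjoint_hotspots_both_present(self):
        a = np.zeros((4, 4)); a[0, 0] = 5.0
        b = np.zeros((4, 4)); b[3, 3] = 7.0
        out = th.max_projection([self.make_map(a), self.make_map(b, dynamic=1)])
        assert out.delta_t_c[0, 0] == 5.0
        assert out.delta_t_c[3, 3] == 7.0

    def test_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(0)
        maps = [self.make_map(rng.normal(size=(5, 5)), dynamic=i)
                for i in range(4)]
        fwd = th.max_projection(maps)
        rev = th.max_projection(maps[::-1])
        np.testing.assert_array_equal(fwd.delta_t_c, rev.delta_t_c)
        extended = th.max_projection(maps + [self.make_map(
            rng.normal(size=(5, 5)), dynamic=4)])
        assert np.all(extended.delta_t_c >= fwd.delta_t_c - 1e-15)

    def test_invalid_pixels_ignored(self):
        a = np.full((2, 2), 3.0)
        mask = np.array([[True, False], [True, True]])
        hot = self.make_map(np.full((2, 2), 9.0), valid=~mask, dynamic=1)
        out = th.max_projection([self.make_map(a, valid=mask), hot])
        assert out.delta_t_c[0, 0] == 3.0   # hot map invalid there
        assert out.delta_t_c[0, 1] == 9.0
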
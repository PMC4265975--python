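"""Virtual scanner: signal model and stream semantics."""

import numpy as np
import pytest

from sonasim import phantoms
from sonasim import scanner as sc
from sonasim.bioheat import TemperatureField
from sonasim.grids import Grid3D


@pytest.fixture()
def block():
    return phantoms.polymer_block_phantom(extent_mm=(80, 80, 40),
                                          spacing_mm=2.0)


@pytest.fixture()
def params():
    return sc.SequenceParams(fov_mm=64, matrix=64, pixel_mm=1.0,
                             slice_thickness_mm=5.0, te_ms=20.0, tr_ms=30.0,
                             dynamic_time_s=0.59, b0_t=3.0)


@pytest.fixture()
def stack():
    return sc.StackGeometry(center_mm=(0.0, 0.0, 0.0))


def uniform_temperature(delta_c, baseline_c=20.0):
    grid = Grid3D(origin_mm=(-40.0, -40.0, -10.0), spacing_mm=2.0,
                  shape=(41, 41, 11))
    return TemperatureField(grid, np.full(grid.shape, baseline_c + delta_c),
                            0.0)


class TestSynthesis:
    def test_no_heating_no_drift_means_zero_phase(self, block, params, stack):
        frame = sc.synthesize_frame(block, None, stack, params)
        np.testing.assert_allclose(frame.phase_rad, 0.0, atol=1e-12)

    def test_prfs_phase_for_uniform_10c(self, block, params, stack):
        """A uniform 10-degC rise at TE=20 ms, 3 T, water fraction 1 gives
        phase 2*pi*gamma*B0*alpha*TE*dT = -1.605 rad."""
        frame = sc.synthesize_frame(block, uniform_temperature(10.0), stack,
                                    params)
        expected = (2 * np.pi * 42.576e6 * 3.0 * (-0.01e-6) * 0.02 * 10.0)
        assert expected == pytest.approx(-1.605, abs=2e-3)
        np.testing.assert_allclose(frame.phase_rad, expected, atol=1e-9)

    def test_fat_contributes_no_prfs_phase(self, params, stack):
        femur = phantoms.femur_phantom()
        frame = sc.synthesize_frame(femur, uniform_temperature(10.0), stack,
                                    params)
        # marrow core: water fraction 0.05 -> 5% of the full phase
        full = 2 * np.pi * 42.576e6 * 3.0 * (-0.01e-6) * 0.02 * 10.0
        assert abs(frame.phase_rad[32, 32]) == pytest.approx(
            abs(full) * 0.05, rel=1e-6)

    def test_marrow_t2_rises_with_temperature(self, stack):
        """With the 20 ms/degC calibration a 5-degC rise lifts marrow T2
        by 100 ms, visible in the two-echo magnitude ratio."""
        femur = phantoms.femur_phantom()
        p2 = sc.SequenceParams(fov_mm=60, matrix=40, pixel_mm=1.5,
                               slice_thickness_mm=5.0, te_ms=40.0,
                               tr_ms=2400.0, dynamic_time_s=9.7,
                               te2_ms=180.0)
        cold = sc.synthesize_frame(femur, None, stack, p2)
        hot = sc.synthesize_frame(femur, uniform_temperature(5.0), stack, p2)

        def t2_center(frame):
            s1, s2 = frame.magnitudes[0][20, 20], frame.magnitudes[1][20, 20]
            return (180.0 - 40.0) / np.log(s1 / s2)

        assert t2_center(cold) == pytest.approx(100.0, rel=1e-9)
        assert t2_center(hot) == pytest.approx(200.0, rel=1e-9)

    def test_slice_outside_phantom_is_zeros(self, block, params):
        far = sc.StackGeometry(center_mm=(0.0, 0.0, 500.0))
        frame = sc.synthesize_frame(block, None, far, params)
        assert not frame.magnitudes[0].any()

    def test_phase_always_in_wrap_interval(self, block, params, stack):
        frame = sc.synthesize_frame(block, uniform_temperature(-40.0), stack,
                                    params, drift_rad=2.5)
        assert np.all(frame.phase_rad > -np.pi)
        assert np.all(frame.phase_rad <= np.pi)

    def test_noiseless_synthesis_deterministic(self, block, params, stack):
        a = sc.synthesize_frame(block, uniform_temperature(3.0), stack, params)
        b = sc.synthesize_frame(block, uniform_temperature(3.0), stack, params)
        np.testing.assert_array_equal(a.phase_rad, b.phase_rad)
        np.testing.assert_array_equal(a.magnitudes[0], b.magnitudes[0])


class TestStream:
    def make(self, block, params, **kw):
        return sc.VirtualScanner(block, params, **kw)

    def test_fifo_order(self, block, params):
        scanner = self.make(block, params)
        h = scanner.subscribe()
        scanner.advance(3 * params.dynamic_time_s + 0.01)
        dynamics = [scanner.query_new_image(h).dynamic for _ in range(3)]
        assert dynamics == [0, 1, 2]
        assert scanner.query_new_image(h) is None

    def test_timestamps_advance_by_dynamic_time(self, block, params):
        scanner = self.make(block, params)
        h = scanner.subscribe()
        scanner.advance(5 * params.dynamic_time_s)
        times = []
        while (f := scanner.query_new_image(h)) is not None:
            times.append(f.acq_time_s)
        np.testing.assert_allclose(np.diff(times), params.dynamic_time_s)

    def test_multiple_subscribers_each_get_every_frame(self, block, params):
        scanner = self.make(block, params)
        h1, h2 = scanner.subscribe(), scanner.subscribe()
        scanner.advance(5 * params.dynamic_time_s + 0.01)
        assert scanner.queue_length(h1) == 5
        assert scanner.queue_length(h2) == 5

    def test_unsubscribe_stops_delivery_and_query_errors(self, block, params):
        scanner = self.make(block, params)
        h = scanner.subscribe()
        scanner.unsubscribe(h)
        with pytest.raises(sc.ScannerError):
            scanner.query_new_image(h)

    def test_query_before_subscribe_errors(self, block, params):
        with pytest.raises(sc.ScannerError):
            self.make(block, params).query_new_image(1)

    def test_continuous_querying_keeps_queue_at_most_one(self, block, params):
        scanner = self.make(block, params)
        h = scanner.subscribe()
        for _ in range(40):
            scanner.advance(0.2)
            assert scanner.queue_length(h) <= 1
            scanner.query_new_image(h)

    def test_pause_resume_numbering_without_gaps(self, block, params):
        scanner = self.make(block, params)
        h = scanner.subscribe()
        scanner.advance(2 * params.dynamic_time_s + 0.01)
        scanner.pause_scan(h)
        scanner.pause_scan(h)  # pausing twice is a no-op
        n_before = scanner.queue_length(h)
        scanner.advance(10.0)
        assert scanner.queue_length(h) == n_before  # nothing while paused
        scanner.resume_scan(h)
        scanner.advance(params.dynamic_time_s + 0.01)
        dynamics = []
        while (f := scanner.query_new_image(h)) is not None:
            dynamics.append(f.dynamic)
        assert dynamics == [0, 1, 2]  # consecutive across the pause

    def test_stack_shift_moves_content(self, params):
        # an off-centre blob: shifting the stack +10 mm LR shifts the image
        phantom = phantoms.polymer_block_phantom(extent_mm=(80, 80, 40),
                                                 spacing_mm=2.0)
        pd = phantom.proton_density.copy()
        xx, yy, _ = np.meshgrid(*phantom.grid.axes_mm(), indexing="ij")
        pd += 2.0 * ((np.abs(xx - 10.0) < 6) & (np.abs(yy) < 6))
        phantom = sc.Phantom(grid=phantom.grid, proton_density=pd,
                             t2_ms=phantom.t2_ms,
                             t2_slope_ms_per_c=phantom.t2_slope_ms_per_c,
                             water_fraction=phantom.water_fraction,
                             baseline_temp_c=phantom.baseline_temp_c,
                             labels=phantom.labels)
        scanner = sc.VirtualScanner(phantom, params)
        h = scanner.subscribe()
        scanner.advance(params.dynamic_time_s)
        base = scanner.query_new_image(h).magnitudes[0]
        scanner.set_stack_geometry(
            h, sc.StackGeometry(center_mm=(10.0, 0.0, 0.0)))
        scanner.advance(params.dynamic_time_s)
        shifted = scanner.query_new_image(h).magnitudes[0]
        # +10 mm LR at 1-mm pixels: content appears 10 rows earlier
        np.testing.assert_allclose(shifted[:-10, :], base[10:, :], atol=1e-9)

    def test_identity_stack_update_changes_nothing(self, block, params):
        scanner = self.make(block, params)
        h = scanner.subscribe()
        scanner.advance(params.dynamic_time_s)
        a = scanner.query_new_image(h).magnitudes[0]
        scanner.set_stack_geometry(h, sc.StackGeometry((0.0, 0.0, 0.0)))
        scanner.advance(params.dynamic_time_s)
        b = scanner.query_new_image(h).magnitudes[0]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_non_orthonormal_axes_rejected(self, block, params):
        with pytest.raises(sc.ScannerError):
            sc.StackGeometry(center_mm=(0, 0, 0),
                             axes=np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1]]))
        with pytest.raises(sc.ScannerError):  # left-handed
            sc.StackGeometry(center_mm=(0, 0, 0),
                             axes=np.diag([1.0, 1.0, -1.0]))

    def test_volume_ordered_by_type_stack_slice(self, block, params):
        stacks = [
            sc.StackGeometry((0.0, 0.0, 0.0), n_slices=3, slice_spacing_mm=5),
            sc.StackGeometry((0.0, 0.0, 10.0), n_slices=3, slice_spacing_mm=5),
        ]
        scanner = sc.VirtualScanner(block, params, stacks=stacks,
                                    image_types=("T1w", "T2w"))
        h = scanner.subscribe()
        frames = scanner.acquire_volume(h)
        assert len(frames) == 12  # 2 types x 2 stacks x 3 slices
        keys = [f.sort_key() for f in frames]
        assert keys == sorted(keys)
        again = [f.sort_key() for f in scanner.acquire_volume(h)]
        assert again == keys  # ordering stable under repetition
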
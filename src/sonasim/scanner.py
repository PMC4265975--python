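"""Virtual MR scanner: image synthesis from a digital phantom plus a
temperature field, and the real-time stream interface (subscribe / query /
pause / resume / stack repositioning / volumetric ordering / queue
semantics).

Signal model
------------
Each pixel is sampled from the phantom by trilinear interpolation.  For a
temperature change ``dT`` relative to the phantom baseline:

* phase (water only):  ``phi = wrap(2 pi gamma B0 alpha TE dT * wf + drift)``
  with the proton-resonance-frequency-shift coefficient
  ``alpha = -0.01 ppm/degC``, ``gamma = 42.576 MHz/T`` and ``wf`` the water
  fraction (fat, e.g. marrow, contributes no PRFS phase — that is why
  T2-based thermometry exists for those tissues);
* magnitude per echo: ``S_e = PD * exp(-TE_e / T2(T))`` with
  ``T2(T) = T2_baseline + slope * dT`` (linear fat calibration);
* complex Gaussian noise is added before magnitude/phase extraction.

B0 drift is injected as a spatially uniform phase per dynamic, linear in
dynamic number by default.  No k-space simulation: ETL, NEX and flip angle
are carried as metadata only.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .bioheat import TemperatureField
from .grids import Grid3D
from .utils import wrap_phase

GAMMA_MHZ_T = 42.576
ALPHA_PRFS_PPM_C = -0.01

SOFT_TISSUE, CORTICAL_BONE, MARROW, POLYMER_PHANTOM, WATER_BATH = range(5)
LABEL_NAMES = {
    SOFT_TISSUE: "soft tissue",
    CORTICAL_BONE: "cortical bone",
    MARROW: "marrow",
    POLYMER_PHANTOM: "polymer phantom",
    WATER_BATH: "water",
}


class ScannerError(RuntimeError):
    """Invalid stream operation (unknown handle, bad geometry, ...)."""


@dataclass(frozen=True)
class Phantom:
    """Digital phantom: 3-D property maps on a grid.

    ``water_fraction`` gates the PRFS phase (1 for aqueous tissue, ~0 for
    fat/marrow); ``t2_slope_ms_per_c`` is the linear temperature
    sensitivity of T2, relevant in fatty tissue.
    """

    grid: Grid3D
    proton_density: np.ndarray
    t2_ms: np.ndarray
    t2_slope_ms_per_c: np.ndarray
    water_fraction: np.ndarray
    baseline_temp_c: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        for name in ("proton_density", "t2_ms", "t2_slope_ms_per_c",
                     "water_fraction", "labels"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match the grid")
            object.__setattr__(self, name, arr)
        wf = self.water_fraction
        if np.any((wf < 0) | (wf > 1)):
            raise ValueError("water_fraction must lie in [0, 1]")
        if np.any(self.t2_ms[self.proton_density > 0] <= 0):
            raise ValueError("T2 must be positive where proton density > 0")


@dataclass(frozen=True)
class SequenceParams:
    """MR sequence metadata; only TE/TR/B0/dynamic_time/matrix/FOV shape
    the synthesized signal, the rest is carried for completeness."""

    fov_mm: float
    matrix: int
    pixel_mm: float
    slice_thickness_mm: float
    te_ms: float
    tr_ms: float
    dynamic_time_s: float
    b0_t: float = 3.0
    te2_ms: Optional[float] = None
    flip_deg: float = 19.5
    etl: int = 1
    nex: int = 1

    def __post_init__(self) -> None:
        for name in ("fov_mm", "matrix", "pixel_mm", "slice_thickness_mm",
                     "te_ms", "tr_ms", "dynamic_time_s", "b0_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.te_ms >= self.tr_ms:
            raise ValueError("TE must be smaller than TR")
        if self.te2_ms is not None and self.te2_ms <= self.te_ms:
            raise ValueError("TE2 must exceed TE1")

    @property
    def echo_times_ms(self) -> tuple[float, ...]:
        return (self.te_ms,) if self.te2_ms is None else (self.te_ms, self.te2_ms)


@dataclass(frozen=True)
class StackGeometry:
    """Imaging stack: centre, right-handed orthonormal axes (rows: in-plane
    row direction, in-plane column direction, slice normal), slice count
    and spacing."""

    center_mm: tuple[float, float, float]
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    n_slices: int = 1
    slice_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        ax = np.asarray(self.axes, dtype=float)
        if ax.shape != (3, 3) or not np.allclose(ax @ ax.T, np.eye(3), atol=1e-8):
            raise ScannerError("stack axes must be orthonormal")
        if np.linalg.det(ax) < 0:
            raise ScannerError("stack axes must be right-handed")
        object.__setattr__(self, "axes", ax)
        object.__setattr__(self, "center_mm",
                           tuple(float(v) for v in self.center_mm))
        if self.n_slices < 1 or self.slice_spacing_mm <= 0:
            raise ScannerError("need n_slices >= 1 and positive slice spacing")


@dataclass(frozen=True)
class ImageFrame:
    """One dynamic MR image: magnitude per echo plus a phase image."""

    magnitudes: tuple[np.ndarray, ...]
    phase_rad: np.ndarray
    image_type: str
    stack_id: int
    slice_number: int
    dynamic: int
    acq_time_s: float
    geometry: StackGeometry
    params: SequenceParams

    def sort_key(self) -> tuple:
        return (self.image_type, self.stack_id, self.slice_number)


def _sample(volume: np.ndarray, grid: Grid3D, points_mm: np.ndarray,
            cval: float = 0.0) -> np.ndarray:
    idx = grid.world_to_index(points_mm)
    return ndimage.map_coordinates(np.asarray(volume, dtype=float), idx.T,
                                   order=1, mode="constant", cval=cval)


def _pixel_points_mm(stack: StackGeometry, params: SequenceParams,
                     slice_number: int) -> np.ndarray:
    n = params.matrix
    i = (np.arange(n) - (n - 1) / 2.0) * params.pixel_mm
    uu, vv = np.meshgrid(i, i, indexing="ij")
    slice_off = (slice_number - (stack.n_slices - 1) / 2.0) * stack.slice_spacing_mm
    pts = (np.asarray(stack.center_mm)
           + uu.ravel()[:, None] * stack.axes[0]
           + vv.ravel()[:, None] * stack.axes[1]
           + slice_off * stack.axes[2])
    return pts


def synthesize_frame(phantom: Phantom,
                     temperature: Optional[TemperatureField],
                     stack: StackGeometry, params: SequenceParams,
                     slice_number: int = 0, dynamic: int = 0,
                     acq_time_s: float = 0.0, drift_rad: float = 0.0,
                     noise_sd: float = 0.0,
                     rng: Optional[np.random.Generator] = None,
                     stack_id: int = 0,
                     image_type: str = "mag_phase") -> ImageFrame:
    """Synthesize one frame.  A slice outside the phantom yields zeros
    (not an error); ``temperature=None`` means baseline everywhere."""
    n = params.matrix
    pts = _pixel_points_mm(stack, params, slice_number)
    pd = _sample(phantom.proton_density, phantom.grid, pts)
    t2b = _sample(phantom.t2_ms, phantom.grid, pts)
    slope = _sample(phantom.t2_slope_ms_per_c, phantom.grid, pts)
    wf = _sample(phantom.water_fraction, phantom.grid, pts)
    if temperature is not None:
        t_abs = _sample(temperature.values_c, temperature.grid, pts,
                        cval=phantom.baseline_temp_c)
        dT = t_abs - phantom.baseline_temp_c
    else:
        dT = np.zeros(pts.shape[0])
    t2 = np.clip(t2b + slope * dT, 1e-3, None)
    phi = wrap_phase(
        2.0 * np.pi * GAMMA_MHZ_T * 1e6 * params.b0_t
        * ALPHA_PRFS_PPM_C * 1e-6 * params.te_ms * 1e-3 * dT * wf
        + drift_rad
    )
    mags, phase_out = [], None
    for te in params.echo_times_ms:
        mag = np.where(pd > 0, pd * np.exp(-te / t2), 0.0)
        signal = mag * np.exp(1j * phi)
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            signal = signal + noise_sd * (
                rng.normal(size=mag.shape) + 1j * rng.normal(size=mag.shape)
            )
        mags.append(np.abs(signal).reshape(n, n))
        if phase_out is None:
            phase_out = wrap_phase(np.angle(signal)).reshape(n, n)
    return ImageFrame(magnitudes=tuple(mags), phase_rad=phase_out,
                      image_type=image_type, stack_id=stack_id,
                      slice_number=slice_number, dynamic=dynamic,
                      acq_time_s=acq_time_s, geometry=stack, params=params)


class VirtualScanner:
    """Dynamic image stream with the real-world queue semantics.

    Frames are produced every ``dynamic_time`` of simulated time (driven
    by :meth:`advance`) and pushed to every subscriber's FIFO queue; a
    consumer that keeps querying holds the queue at length <= 1.  Any
    subscriber may pause/resume the acquisition and reposition stacks in
    real time; dynamic numbering continues without gaps across pauses.
    """

    def __init__(self, phantom: Phantom, params: SequenceParams,
                 stacks: Optional[Sequence[StackGeometry]] = None,
                 temperature_provider: Optional[Callable[[float], Optional[TemperatureField]]] = None,
                 image_types: Sequence[str] = ("mag_phase",),
                 drift_rad_per_dynamic: float = 0.02,
                 noise_sd: float = 0.0, seed: int = 0) -> None:
        self.phantom = phantom
        self.params = params
        self.stacks = list(stacks) if stacks is not None else [
            StackGeometry(center_mm=(0.0, 0.0, 0.0))
        ]
        self.temperature_provider = temperature_provider
        self.image_types = tuple(image_types)
        self.drift_rad_per_dynamic = float(drift_rad_per_dynamic)
        self.noise_sd = float(noise_sd)
        self.seed = int(seed)

        self._t = 0.0
        self._next_acq = params.dynamic_time_s
        self._dynamic = 0
        self._paused = False
        self._queues: dict[int, deque] = {}
        self._next_handle = 1
        self.frames_produced = 0

    # -- stream interface --------------------------------------------------

    def subscribe(self) -> int:
        handle = self._next_handle
        self._next_handle += 1
        self._queues[handle] = deque()
        return handle

    def unsubscribe(self, handle: int) -> None:
        self._require(handle)
        del self._queues[handle]

    def query_new_image(self, handle: int) -> Optional[ImageFrame]:
        """Pull the oldest image from the subscriber's queue; None when
        empty.  Non-blocking."""
        self._require(handle)
        q = self._queues[handle]
        return q.popleft() if q else None

    def queue_length(self, handle: int) -> int:
        self._require(handle)
        return len(self._queues[handle])

    def pause_scan(self, handle: int) -> None:
        self._require(handle)
        self._paused = True

    def resume_scan(self, handle: int) -> None:
        self._require(handle)
        if self._paused:
            self._paused = False
            self._next_acq = self._t + self.params.dynamic_time_s

    def set_stack_geometry(self, handle: int, stack: StackGeometry,
                           stack_id: int = 0) -> None:
        """Reposition/reorient a stack; takes effect from the next frame."""
        self._require(handle)
        if not isinstance(stack, StackGeometry):
            stack = StackGeometry(*stack)
        if not (0 <= stack_id < len(self.stacks)):
            raise ScannerError(f"no stack with id {stack_id}")
        self.stacks[stack_id] = stack

    def advance(self, dt_s: float) -> int:
        """Advance the scanner clock; returns the number of frames
        produced.  Frame timestamps advance by exactly ``dynamic_time``
        while running."""
        if dt_s < 0:
            raise ValueError("dt_s must be >= 0")
        target = self._t + dt_s
        produced = 0
        while not self._paused and self._next_acq <= target + 1e-12:
            self._t = self._next_acq
            self._emit_dynamic()
            produced += 1
            self._next_acq += self.params.dynamic_time_s
        self._t = target
        return produced

    def acquire_volume(self, handle: int) -> list[ImageFrame]:
        """Synthesize one full volume now, ordered by (type, stack,
        slice)."""
        self._require(handle)
        frames = self._synthesize_all(self._dynamic)
        self._dynamic += 1
        return sorted(frames, key=lambda f: f.sort_key())

    @property
    def clock_s(self) -> float:
        return self._t

    @property
    def next_dynamic(self) -> int:
        return self._dynamic

    # -- internals ---------------------------------------------------------

    def _require(self, handle: int) -> None:
        if handle not in self._queues:
            raise ScannerError(f"handle {handle} is not subscribed")

    def _emit_dynamic(self) -> None:
        frames = sorted(self._synthesize_all(self._dynamic),
                        key=lambda f: f.sort_key())
        self._dynamic += 1
        for q in self._queues.values():
            q.extend(frames)
        self.frames_produced += len(frames)

    def _synthesize_all(self, dynamic: int) -> list[ImageFrame]:
        temp = (self.temperature_provider(self._t)
                if self.temperature_provider is not None else None)
        drift = self.drift_rad_per_dynamic * dynamic
        frames = []
        for ti, image_type in enumerate(self.image_types):
            for si, stack in enumerate(self.stacks):
                for sl in range(stack.n_slices):
                    rng = np.random.default_rng(
                        [self.seed, dynamic, ti, si, sl]
                    ) if self.noise_sd > 0 else None
                    frames.append(synthesize_frame(
                        self.phantom, temp, stack, self.params,
                        slice_number=sl, dynamic=dynamic,
                        acq_time_s=self._t, drift_rad=drift,
                        noise_sd=self.noise_sd, rng=rng, stack_id=si,
                        image_type=image_type,
                    ))
        return frames
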
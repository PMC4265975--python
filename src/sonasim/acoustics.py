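"""Virtual phased-array transducer: element layout, Rayleigh-integral
pressure fields, electronic steering, heat deposition and a virtual
hydrophone.

The modelled device is a 256-element spherical-shell array with a 12-cm
focal length and 13-cm aperture operating between 1.0 and 1.5 MHz.  The
true element arrangement of the hardware is proprietary, so elements are
packed deterministically on the spherical cap with a sunflower (golden
angle) spiral; the layout is pluggable through :func:`layout_elements`
arguments.

Fields are computed with the Rayleigh-Sommerfeld integral over each
element's discretized surface,

    p(r) = (i rho c k u0 / 2 pi) * sum_patches exp(-(i k + alpha) d) / d * dS,

with ``alpha`` the amplitude attenuation (Np/m) at the drive frequency.
Element surfaces are treated as flat discs in their tangent planes and
discretized into patches no larger than a quarter wavelength at 1.5 MHz by
default.  The model is linear: no nonlinear propagation, cavitation,
refraction or element cross-talk; a single homogeneous medium per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grids import Grid3D
from .utils import wrap_phase


@dataclass(frozen=True)
class MediumProperties:
    """Homogeneous acoustic medium.

    ``attenuation_np_m_mhz`` is the amplitude attenuation coefficient per
    MHz; ``absorption_fraction`` is the share of attenuated energy that is
    deposited locally as heat (the rest is treated as scattered away).
    """

    sound_speed_m_s: float = 1500.0
    density_kg_m3: float = 1000.0
    attenuation_np_m_mhz: float = 0.0
    absorption_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.sound_speed_m_s <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("sound speed and density must be positive")
        if self.attenuation_np_m_mhz < 0 or not (0 <= self.absorption_fraction <= 1):
            raise ValueError("invalid attenuation/absorption")

    def wavenumber(self, frequency_mhz: float) -> float:
        return 2.0 * np.pi * frequency_mhz * 1e6 / self.sound_speed_m_s

    def attenuation_np_m(self, frequency_mhz: float) -> float:
        return self.attenuation_np_m_mhz * frequency_mhz


WATER = MediumProperties(sound_speed_m_s=1500.0, density_kg_m3=1000.0,
                         attenuation_np_m_mhz=0.025, absorption_fraction=1.0)

#: Tissue-mimicking phantom: 0.5 dB/cm/MHz amplitude attenuation
#: (5.76 Np/m/MHz), most of it absorbed.
PHANTOM_MEDIUM = MediumProperties(sound_speed_m_s=1540.0, density_kg_m3=1045.0,
                                  attenuation_np_m_mhz=5.76,
                                  absorption_fraction=0.9)


@dataclass(frozen=True)
class ArrayGeometry:
    """Spherical-shell array; the geometric (natural) focus is the origin
    of the device frame and elements sit at ``focal_length_mm`` from it
    with negative beam-axis coordinates."""

    element_centers_mm: np.ndarray  # (N, 3)
    element_normals: np.ndarray     # (N, 3), unit, toward the focus
    element_radius_mm: float
    focal_length_mm: float
    aperture_diameter_mm: float

    @property
    def n_elements(self) -> int:
        return self.element_centers_mm.shape[0]

    def __post_init__(self) -> None:
        c = np.asarray(self.element_centers_mm, dtype=float)
        n = np.asarray(self.element_normals, dtype=float)
        object.__setattr__(self, "element_centers_mm", c)
        object.__setattr__(self, "element_normals", n)
        r = np.linalg.norm(c, axis=1)
        if not np.allclose(r, self.focal_length_mm, rtol=1e-6):
            raise ValueError("element centers must lie on the focal shell")
        if not np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9):
            raise ValueError("element normals must be unit length")

    @property
    def element_area_m2(self) -> float:
        return np.pi * (self.element_radius_mm * 1e-3) ** 2


def layout_elements(n_elements: int = 256, focal_length_mm: float = 120.0,
                    aperture_diameter_mm: float = 130.0,
                    element_radius_mm: Optional[float] = None,
                    fill_fraction: float = 0.6, seed: int = 0) -> ArrayGeometry:
    """Deterministic sunflower-spiral packing of ``n_elements`` on the
    spherical cap.  ``seed`` rotates the spiral start (same seed, same
    layout).  Default element radius fills ``fill_fraction`` of the cap."""
    F = float(focal_length_mm)
    sin_max = (aperture_diameter_mm / 2.0) / F
    if not (0 < sin_max <= 1):
        raise ValueError("aperture incompatible with focal length")
    cos_max = np.sqrt(1.0 - sin_max ** 2)
    i = np.arange(n_elements)
    if n_elements == 1:
        cos_t = np.array([1.0])
    else:
        # area-uniform in cos(theta) over the cap
        cos_t = 1.0 - (1.0 - cos_max) * (i + 0.5) / n_elements
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    rng = np.random.default_rng(seed)
    phi = i * golden + rng.uniform(0.0, 2.0 * np.pi)
    centers = F * np.column_stack([sin_t * np.cos(phi),
                                   sin_t * np.sin(phi),
                                   -cos_t])
    normals = -centers / F
    if element_radius_mm is None:
        cap_area = 2.0 * np.pi * F ** 2 * (1.0 - cos_max)
        element_radius_mm = np.sqrt(fill_fraction * cap_area / (n_elements * np.pi))
    return ArrayGeometry(element_centers_mm=centers, element_normals=normals,
                         element_radius_mm=float(element_radius_mm),
                         focal_length_mm=F,
                         aperture_diameter_mm=float(aperture_diameter_mm))


@dataclass(frozen=True)
class DriveVector:
    """Per-element complex drive: amplitude fractions in [0, 1], phases in
    radians, an active mask, and the drive frequency."""

    amplitudes: np.ndarray
    phases_rad: np.ndarray
    active: np.ndarray
    frequency_mhz: float

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        p = np.asarray(self.phases_rad, dtype=float)
        m = np.asarray(self.active, dtype=bool)
        if not (a.shape == p.shape == m.shape):
            raise ValueError("drive arrays must share one length")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("amplitudes must lie in [0, 1]")
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "phases_rad", p)
        object.__setattr__(self, "active", m)

    @property
    def n_elements(self) -> int:
        return self.amplitudes.shape[0]

    @classmethod
    def uniform(cls, n_elements: int, frequency_mhz: float) -> "DriveVector":
        return cls(np.ones(n_elements), np.zeros(n_elements),
                   np.ones(n_elements, dtype=bool), frequency_mhz)

    @classmethod
    def single_element(cls, n_elements: int, element: int,
                       frequency_mhz: float) -> "DriveVector":
        active = np.zeros(n_elements, dtype=bool)
        active[element] = True
        return cls(np.ones(n_elements), np.zeros(n_elements), active,
                   frequency_mhz)


def default_patch_size_mm(medium: MediumProperties) -> float:
    """Quarter wavelength at 1.5 MHz — the documented discretization bound."""
    return medium.sound_speed_m_s / 1.5e6 / 4.0 * 1e3


def _disc_patches(radius_mm: float, max_patch_mm: float):
    """Polar-grid patches of a disc in its local (e1, e2) plane: returns
    in-plane coordinates (M, 2) in mm and areas (M,) in mm^2."""
    n_rings = max(1, int(np.ceil(radius_mm / max_patch_mm)))
    dr = radius_mm / n_rings
    coords, areas = [(0.0, 0.0)], [np.pi * (dr / 2.0) ** 2]
    for j in range(1, n_rings + 1):
        r = (j - 0.5) * dr
        n_az = max(6, int(np.ceil(2.0 * np.pi * r / max_patch_mm)))
        ang = 2.0 * np.pi * np.arange(n_az) / n_az
        ring_area = np.pi * ((j * dr) ** 2 - ((j - 1) * dr) ** 2) - (
            np.pi * (dr / 2.0) ** 2 if j == 1 else 0.0
        )
        for a in ang:
            coords.append((r * np.cos(a), r * np.sin(a)))
            areas.append(ring_area / n_az)
    return np.asarray(coords), np.asarray(areas)


def _element_patches(geometry: ArrayGeometry, element: int,
                     max_patch_mm: float):
    """World-frame patch centres (M, 3) mm and areas (M,) m^2 of one
    element, laid flat in the element's tangent plane."""
    center = geometry.element_centers_mm[element]
    normal = geometry.element_normals[element]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    local, areas_mm2 = _disc_patches(geometry.element_radius_mm, max_patch_mm)
    world = center + local[:, :1] * e1 + local[:, 1:2] * e2
    return world, areas_mm2 * 1e-6


def _rayleigh_sum(patch_pos_mm: np.ndarray, patch_weight: np.ndarray,
                  points_mm: np.ndarray, k_m: float, alpha_np_m: float,
                  prefactor: complex, d_min_m: float,
                  chunk_elems: int = 4_000_000) -> np.ndarray:
    """Accumulate prefactor * sum_j w_j exp(-(ik+alpha) d_ij)/d_ij over
    patches j for every point i, chunking to bound memory."""
    points_m = np.atleast_2d(points_mm) * 1e-3
    patches_m = patch_pos_mm * 1e-3
    n_pts = points_m.shape[0]
    n_patch = patches_m.shape[0]
    out = np.zeros(n_pts, dtype=complex)
    block = max(1, int(chunk_elems // max(n_patch, 1)))
    for start in range(0, n_pts, block):
        sl = slice(start, start + block)
        d = np.linalg.norm(points_m[sl, None, :] - patches_m[None, :, :], axis=2)
        np.maximum(d, d_min_m, out=d)
        contrib = patch_weight[None, :] * np.exp(-(1j * k_m + alpha_np_m) * d) / d
        out[sl] = prefactor * contrib.sum(axis=1)
    return out


def element_field(geometry: ArrayGeometry, element: int, points_mm,
                  frequency_mhz: float, medium: MediumProperties = WATER,
                  u0_m_s: float = 1.0,
                  max_patch_mm: Optional[float] = None) -> np.ndarray:
    """Complex pressure (Pa) of one element at ``points_mm`` for surface
    velocity amplitude ``u0_m_s``.  Field points closer to a source patch
    than the patch's equivalent radius use a regularized distance."""
    if max_patch_mm is None:
        max_patch_mm = default_patch_size_mm(medium)
    patches, areas_m2 = _element_patches(geometry, element, max_patch_mm)
    k = medium.wavenumber(frequency_mhz)
    alpha = medium.attenuation_np_m(frequency_mhz)
    pref = 1j * medium.density_kg_m3 * medium.sound_speed_m_s * k * u0_m_s \
        / (2.0 * np.pi)
    d_min = np.sqrt(np.max(areas_m2) / np.pi)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    out = _rayleigh_sum(patches, areas_m2, pts, k, alpha, pref, d_min)
    return out if np.asarray(points_mm).ndim > 1 else out[0]


def steering_phases(geometry: ArrayGeometry, focus_offset_mm,
                    frequency_mhz: float,
                    medium: MediumProperties = WATER) -> np.ndarray:
    """Per-element phases (rad, wrapped to (-pi, pi]) that relocate the
    focus to ``focus_offset_mm`` from the natural focus:
    phi_n = k (|r_n - r_f| - F)."""
    k_mm = medium.wavenumber(frequency_mhz) * 1e-3
    r_f = np.asarray(focus_offset_mm, dtype=float)
    d = np.linalg.norm(geometry.element_centers_mm - r_f[None, :], axis=1)
    return wrap_phase(k_mm * (d - geometry.focal_length_mm))


def array_field(geometry: ArrayGeometry, drive: DriveVector, points_mm,
                medium: MediumProperties = WATER, u0_m_s: float = 1.0,
                max_patch_mm: Optional[float] = None) -> np.ndarray:
    """Superposed complex pressure of all active elements (Pa)."""
    if drive.n_elements != geometry.n_elements:
        raise ValueError("drive length does not match the array")
    if max_patch_mm is None:
        max_patch_mm = default_patch_size_mm(medium)
    k = medium.wavenumber(drive.frequency_mhz)
    alpha = medium.attenuation_np_m(drive.frequency_mhz)
    pref = 1j * medium.density_kg_m3 * medium.sound_speed_m_s * k * u0_m_s \
        / (2.0 * np.pi)
    all_patches, all_weights = [], []
    for n in np.flatnonzero(drive.active):
        patches, areas = _element_patches(geometry, n, max_patch_mm)
        w = areas * drive.amplitudes[n] * np.exp(1j * drive.phases_rad[n])
        all_patches.append(patches)
        all_weights.append(w)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if not all_patches:
        out = np.zeros(pts.shape[0], dtype=complex)
    else:
        patches = np.concatenate(all_patches, axis=0)
        weights = np.concatenate(all_weights)
        d_min = np.sqrt(np.max(areas) / np.pi)
        out = _rayleigh_sum(patches, weights, pts, k, alpha, pref, d_min)
    return out if np.asarray(points_mm).ndim > 1 else out[0]


def source_velocity_for_power(geometry: ArrayGeometry, drive: DriveVector,
                              medium: MediumProperties,
                              acoustic_power_w: float) -> float:
    """Surface-velocity amplitude u0 (m/s) that radiates
    ``acoustic_power_w`` for the given drive, from the plane-piston
    radiation impedance: P = sum_n (rho c / 2) (a_n u0)^2 A_n."""
    if acoustic_power_w == 0:
        return 0.0
    a2 = float(np.sum(drive.amplitudes[drive.active] ** 2))
    if a2 == 0:
        raise ValueError("no active elements with nonzero amplitude")
    denom = 0.5 * medium.density_kg_m3 * medium.sound_speed_m_s \
        * a2 * geometry.element_area_m2
    return float(np.sqrt(acoustic_power_w / denom))


def heat_deposition(geometry: ArrayGeometry, drive: DriveVector, grid: Grid3D,
                    medium: MediumProperties, acoustic_power_w: float,
                    max_patch_mm: Optional[float] = None) -> np.ndarray:
    """Volumetric heat source Q (W/m^3) on ``grid``:
    Q = 2 alpha_abs |p|^2 / (2 rho c), with the drive globally scaled so
    the radiated acoustic power equals ``acoustic_power_w``."""
    if acoustic_power_w < 0:
        raise ValueError("acoustic_power_w must be >= 0")
    if acoustic_power_w == 0:
        return np.zeros(grid.shape)
    u0 = source_velocity_for_power(geometry, drive, medium, acoustic_power_w)
    p = array_field(geometry, drive, grid.points_mm(), medium, u0_m_s=u0,
                    max_patch_mm=max_patch_mm)
    intensity = np.abs(p) ** 2 / (2.0 * medium.density_kg_m3
                                  * medium.sound_speed_m_s)
    alpha_abs = medium.attenuation_np_m(drive.frequency_mhz) \
        * medium.absorption_fraction
    return (2.0 * alpha_abs * intensity).reshape(grid.shape)


@dataclass(frozen=True)
class HydrophoneRecord:
    element: int
    time_s: np.ndarray
    waveform_pa: np.ndarray
    summary_amplitude_pa: float
    averages: int


def hydrophone_record(geometry: ArrayGeometry, element: int, point_mm,
                      frequency_mhz: float = 1.2, cycles: int = 40,
                      averages: int = 64, noise_sd_pa: float = 0.0,
                      seed: int = 0, u0_m_s: float = 1.0,
                      medium: MediumProperties = WATER,
                      samples_per_cycle: int = 16,
                      max_patch_mm: Optional[float] = None) -> HydrophoneRecord:
    """Virtual hydrophone acquisition of one tone burst from one element.

    The steady-state complex pressure at ``point_mm`` defines the burst's
    amplitude and phase; ``averages`` noisy repeats are averaged (additive
    Gaussian noise, variance reduced by 1/averages) and the summary
    amplitude is half the peak-to-peak excursion of the averaged burst.
    """
    p = element_field(geometry, element, np.asarray(point_mm, dtype=float),
                      frequency_mhz, medium, u0_m_s=u0_m_s,
                      max_patch_mm=max_patch_mm)
    f_hz = frequency_mhz * 1e6
    n_samp = cycles * samples_per_cycle
    t = np.arange(n_samp) / (samples_per_cycle * f_hz)
    clean = np.abs(p) * np.sin(2.0 * np.pi * f_hz * t + np.angle(p))
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        reps = clean[None, :] + rng.normal(0.0, noise_sd_pa, (averages, n_samp))
        waveform = reps.mean(axis=0)
    else:
        waveform = clean.copy()
    summary = float((waveform.max() - waveform.min()) / 2.0)
    return HydrophoneRecord(element=int(element), time_s=t,
                            waveform_pa=waveform,
                            summary_amplitude_pa=summary, averages=averages)


def drive_from_engine(engine_state: dict, geometry: ArrayGeometry,
                      medium: MediumProperties = WATER) -> Optional[DriveVector]:
    """Build the instantaneous drive from a :meth:`TreatmentEngine.
    drive_state` snapshot: element overrides plus steering phases for the
    current trajectory point.  Returns None when no exposure is active."""
    exp = engine_state["exposure"]
    if exp is None:
        return None
    phases = steering_phases(geometry, exp["focal_offset_mm"],
                             exp["frequency_mhz"], medium)
    phases = wrap_phase(phases + engine_state["phases_rad"])
    return DriveVector(amplitudes=engine_state["amplitudes"],
                       phases_rad=phases,
                       active=engine_state["active_mask"],
                       frequency_mhz=exp["frequency_mhz"])
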
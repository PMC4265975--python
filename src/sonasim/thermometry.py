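"""MR thermometry: PRFS phase-difference temperature maps with B0-drift
correction, two-echo T2 mapping with linear temperature calibration, and
maximum temperature-change projection.

PRFS
----
The water proton resonance frequency falls by about 0.01 ppm per degC, so
the phase accumulated at echo time TE is a thermometer::

    dT = wrap(phi - phi_ref) / (2 pi gamma B0 alpha_PRFS TE)

Phase differences are wrapped to (-pi, pi] before scaling; changes beyond
+/-pi between frames alias and are out of scope (the magnitude mask is the
only guard).  Pixels with magnitude below a threshold (default 5% of the
frame maximum) are flagged invalid, never silently zeroed.

T2 (fatty tissue)
-----------------
Fat contributes no PRFS phase, so marrow temperature is read from the
linear increase of T2 with temperature: a two-echo estimate
``T2 = (TE2 - TE1) / ln(S1 / S2)`` and ``dT = (T2 - T2_ref) / slope`` with
a calibration slope of about 20 ms/degC in bone marrow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from .scanner import ALPHA_PRFS_PPM_C, GAMMA_MHZ_T, ImageFrame
from .utils import wrap_phase


class ThermometryError(ValueError):
    """Incompatible frames or invalid configuration."""


@dataclass(frozen=True)
class ThermometryConfig:
    alpha_prfs_ppm_c: float = ALPHA_PRFS_PPM_C
    gamma_mhz_t: float = GAMMA_MHZ_T
    b0_t: float = 3.0
    te_ms: float = 20.0
    magnitude_threshold: float = 0.05  # fraction of per-frame max
    t2_slope_ms_per_c: float = 20.0

    def __post_init__(self) -> None:
        if self.alpha_prfs_ppm_c == 0:
            raise ThermometryError("alpha_prfs_ppm_c must be nonzero")
        if self.t2_slope_ms_per_c <= 0:
            raise ThermometryError("t2 slope must be positive")

    def rad_per_degc(self) -> float:
        return (2.0 * np.pi * self.gamma_mhz_t * 1e6 * self.b0_t
                * self.alpha_prfs_ppm_c * 1e-6 * self.te_ms * 1e-3)


@dataclass(frozen=True)
class TemperatureMap:
    """2-D temperature-change map with an explicit validity mask."""

    delta_t_c: np.ndarray
    valid: np.ndarray
    dynamic: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.delta_t_c, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if d.shape != v.shape:
            raise ThermometryError("map and mask shapes differ")
        object.__setattr__(self, "delta_t_c", d)
        object.__setattr__(self, "valid", v)

    def masked(self) -> np.ndarray:
        out = self.delta_t_c.copy()
        out[~self.valid] = np.nan
        return out


def _config_from_frame(frame: ImageFrame,
                       config: Optional[ThermometryConfig]) -> ThermometryConfig:
    if config is None:
        return ThermometryConfig(te_ms=frame.params.te_ms,
                                 b0_t=frame.params.b0_t)
    return replace(config, te_ms=frame.params.te_ms, b0_t=frame.params.b0_t)


def prfs_delta_t(frame: ImageFrame, reference: ImageFrame,
                 config: Optional[ThermometryConfig] = None) -> TemperatureMap:
    """PRFS temperature change of ``frame`` relative to ``reference``.

    Frames must share TE and stack geometry.  If ``config`` is None, TE
    and B0 are taken from the frame metadata with standard constants.
    """
    if frame.params.te_ms != reference.params.te_ms:
        raise ThermometryError(
            f"TE mismatch: {frame.params.te_ms} vs {reference.params.te_ms} ms"
        )
    if not np.allclose(frame.geometry.axes, reference.geometry.axes) or \
            frame.geometry.center_mm != reference.geometry.center_mm:
        raise ThermometryError("frames do not share stack geometry")
    cfg = _config_from_frame(frame, config)
    dphi = wrap_phase(frame.phase_rad - reference.phase_rad)
    delta_t = dphi / cfg.rad_per_degc()
    mag = frame.magnitudes[0]
    valid = mag >= cfg.magnitude_threshold * mag.max() if mag.max() > 0 \
        else np.zeros_like(mag, dtype=bool)
    return TemperatureMap(delta_t_c=delta_t, valid=valid,
                          dynamic=frame.dynamic, time_s=frame.acq_time_s)


def drift_correct(tmap: TemperatureMap, roi_mask: np.ndarray,
                  order: int = 0) -> TemperatureMap:
    """Remove B0 drift using a non-heated reference region.

    ``order=0`` subtracts the ROI mean (the corrected ROI mean is exactly
    zero, so the correction is idempotent); ``order=1`` removes a planar
    fit over the ROI.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != tmap.delta_t_c.shape:
        raise ThermometryError("ROI shape does not match the map")
    use = roi & tmap.valid
    if not use.any():
        raise ThermometryError("drift ROI contains no valid pixels")
    if order == 0:
        corrected = tmap.delta_t_c - tmap.delta_t_c[use].mean()
    elif order == 1:
        ii, jj = np.nonzero(use)
        A = np.column_stack([np.ones_like(ii, dtype=float), ii, jj])
        coef, *_ = np.linalg.lstsq(A, tmap.delta_t_c[use], rcond=None)
        gi, gj = np.mgrid[: tmap.delta_t_c.shape[0], : tmap.delta_t_c.shape[1]]
        corrected = tmap.delta_t_c - (coef[0] + coef[1] * gi + coef[2] * gj)
    else:
        raise ThermometryError("order must be 0 or 1")
    return TemperatureMap(delta_t_c=corrected, valid=tmap.valid,
                          dynamic=tmap.dynamic, time_s=tmap.time_s)


def t2_map(echo1: np.ndarray, echo2: np.ndarray, te1_ms: float,
           te2_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-echo T2 estimate (ms): T2 = (TE2 - TE1) / ln(S1/S2).

    Returns ``(t2_ms, valid)``; pixels with S1 <= S2 or non-positive
    signal are masked invalid rather than raising.
    """
    if te2_ms <= te1_ms:
        raise ThermometryError("TE2 must exceed TE1")
    s1 = np.asarray(echo1, dtype=float)
    s2 = np.asarray(echo2, dtype=float)
    valid = (s1 > 0) & (s2 > 0) & (s1 > s2)
    t2 = np.full(s1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(np.where(valid, s1 / np.where(s2 > 0, s2, 1.0), np.e))
    t2[valid] = (te2_ms - te1_ms) / ratio[valid]
    return t2, valid


def t2_map_from_frame(frame: ImageFrame) -> tuple[np.ndarray, np.ndarray]:
    if len(frame.magnitudes) < 2 or frame.params.te2_ms is None:
        raise ThermometryError("need a two-echo frame")
    return t2_map(frame.magnitudes[0], frame.magnitudes[1],
                  frame.params.te_ms, frame.params.te2_ms)


def t2_to_temp(t2_ms: np.ndarray, t2_ref_ms: np.ndarray,
               slope_ms_per_c: float = 20.0,
               valid: Optional[np.ndarray] = None,
               dynamic: int = 0, time_s: float = 0.0) -> TemperatureMap:
    """Scale a T2 change to temperature: dT = (T2 - T2_ref) / slope."""
    if slope_ms_per_c <= 0:
        raise ThermometryError("slope must be positive")
    t2 = np.asarray(t2_ms, dtype=float)
    ref = np.asarray(t2_ref_ms, dtype=float)
    ok = np.isfinite(t2) & np.isfinite(ref)
    if valid is not None:
        ok = ok & np.asarray(valid, dtype=bool)
    delta = np.where(ok, (t2 - ref) / slope_ms_per_c, 0.0)
    return TemperatureMap(delta_t_c=delta, valid=ok, dynamic=dynamic,
                          time_s=time_s)


def max_projection(maps: Iterable[TemperatureMap]) -> TemperatureMap:
    """Per-pixel maximum temperature change over dynamics, ignoring
    invalid pixels; a pixel is valid in the result if it was valid in any
    input."""
    maps = list(maps)
    if not maps:
        raise ThermometryError("max_projection needs at least one map")
    shape = maps[0].delta_t_c.shape
    best = np.full(shape, -np.inf)
    any_valid = np.zeros(shape, dtype=bool)
    last = maps[0]
    for m in maps:
        if m.delta_t_c.shape != shape:
            raise ThermometryError("maps must share one shape")
        candidate = np.where(m.valid, m.delta_t_c, -np.inf)
        best = np.maximum(best, candidate)
        any_valid |= m.valid
        if m.time_s >= last.time_s:
            last = m
    out = np.where(any_valid, best, 0.0)
    return TemperatureMap(delta_t_c=out, valid=any_valid,
                          dynamic=last.dynamic, time_s=last.time_s)
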
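"""Programmatic phantom generators.

All phantoms are generated at run time (no binary fixtures).  Property
values are representative literature values for the emulated materials;
they define the synthetic study conditions, not measurements.
"""

from __future__ import annotations

import numpy as np

from .grids import centered_grid
from .scanner import (
    CORTICAL_BONE,
    MARROW,
    POLYMER_PHANTOM,
    SOFT_TISSUE,
    Phantom,
)


def polymer_block_phantom(extent_mm=(200.0, 120.0, 60.0), spacing_mm: float = 2.0,
                          baseline_temp_c: float = 20.0,
                          t2_ms: float = 80.0) -> Phantom:
    """Homogeneous polymer tissue-mimicking heating phantom: fully aqueous
    (PRFS applies everywhere), uniform T2, no T2 temperature slope worth
    modelling at mild heating."""
    grid = centered_grid(extent_mm, spacing_mm)
    shape = grid.shape
    return Phantom(
        grid=grid,
        proton_density=np.ones(shape),
        t2_ms=np.full(shape, float(t2_ms)),
        t2_slope_ms_per_c=np.zeros(shape),
        water_fraction=np.ones(shape),
        baseline_temp_c=float(baseline_temp_c),
        labels=np.full(shape, POLYMER_PHANTOM, dtype=np.int8),
    )


def femur_phantom(extent_mm=(80.0, 80.0, 30.0), spacing_mm: float = 1.5,
                  marrow_radius_mm: float = 8.0,
                  cortical_radius_mm: float = 13.0,
                  baseline_temp_c: float = 20.0,
                  marrow_t2_ms: float = 100.0,
                  marrow_slope_ms_per_c: float = 20.0) -> Phantom:
    """Bone cross-section: fatty marrow core (no PRFS phase, strong linear
    T2-temperature dependence), low-signal cortical shell, aqueous soft
    tissue outside.  The marrow slope default is the calibrated
    20 ms/degC."""
    grid = centered_grid(extent_mm, spacing_mm)
    x, y, _ = np.meshgrid(*grid.axes_mm(), indexing="ij")
    r = np.hypot(x, y)
    marrow = r <= marrow_radius_mm
    cortical = (r > marrow_radius_mm) & (r <= cortical_radius_mm)
    soft = r > cortical_radius_mm

    pd = np.where(marrow, 1.0, np.where(cortical, 0.05, 0.9))
    t2 = np.where(marrow, marrow_t2_ms, np.where(cortical, 1.0, 60.0))
    slope = np.where(marrow, marrow_slope_ms_per_c, 0.0)
    wf = np.where(marrow, 0.05, np.where(cortical, 0.2, 0.9))
    labels = np.where(marrow, MARROW,
                      np.where(cortical, CORTICAL_BONE, SOFT_TISSUE)).astype(np.int8)
    return Phantom(grid=grid, proton_density=pd, t2_ms=t2,
                   t2_slope_ms_per_c=slope, water_fraction=wf,
                   baseline_temp_c=float(baseline_temp_c), labels=labels)


def mouse_flank_phantom(extent_mm=(80.0, 80.0, 24.0), spacing_mm: float = 1.0,
                        baseline_temp_c: float = 37.0) -> Phantom:
    """Small-animal soft-tissue block (coronal thermometry target)."""
    grid = centered_grid(extent_mm, spacing_mm)
    shape = grid.shape
    return Phantom(
        grid=grid,
        proton_density=np.ones(shape),
        t2_ms=np.full(shape, 60.0),
        t2_slope_ms_per_c=np.zeros(shape),
        water_fraction=np.ones(shape),
        baseline_temp_c=float(baseline_temp_c),
        labels=np.full(shape, SOFT_TISSUE, dtype=np.int8),
    )
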
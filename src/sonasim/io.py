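"""Writers: NIfTI volumes/movies with JSON sidecars, CSV summaries."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(volume: np.ndarray, spacing_mm, path) -> Path:
    """Write a 3-D or 4-D array as NIfTI with a diagonal affine."""
    path = Path(path)
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    affine = np.diag([*spacing[:3], 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def save_temperature_movie(maps, spacing_mm, path, sidecar=None) -> Path:
    """Stack 2-D temperature maps into one NIfTI (x, y, 1, t) plus a JSON
    sidecar with per-dynamic timestamps."""
    path = Path(path)
    stack = np.stack([m.delta_t_c for m in maps], axis=-1)[:, :, None, :]
    out = save_nifti(stack, spacing_mm, path)
    meta = {
        "timestamps_s": [float(m.time_s) for m in maps],
        "dynamics": [int(m.dynamic) for m in maps],
    }
    if sidecar:
        meta.update(sidecar)
    out.with_suffix("").with_suffix(".json").write_text(
        json.dumps(meta, indent=2)
    )
    return out


def save_scan_records(records: Sequence, path) -> Path:
    """Per-element scan output: element_id, summary_amplitude_Pa,
    timestamp_s."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "element_id": [r.element_id for r in records],
            "summary_amplitude_Pa": [r.summary_amplitude_pa for r in records],
            "timestamp_s": [r.timestamp_s for r in records],
        }
    ).to_csv(path, index=False)
    return path


def save_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path
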
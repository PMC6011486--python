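"""NIfTI + JSON-sidecar serialization.

4D velocity data are stored as three NIfTI volumes (vx, vy, vz; shape
X x Y x Z x T, values m/s) next to a JSON sidecar holding the acquisition
metadata; CINE series as a single-slice NIfTI (X x Y x 1 x T); masks as
0/1 NIfTI volumes; centerlines, contours and results as JSON; cohorts as
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .datatypes import Centerline, CineSeries, LumenMask, VelocityField4D

__all__ = [
    "save_velocity_field",
    "load_velocity_field",
    "save_mask",
    "load_mask",
    "save_cine",
    "load_cine",
    "save_centerline",
    "load_centerline",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_velocity_field(field: VelocityField4D, prefix: str | Path,
                        extra_meta: dict | None = None) -> None:
    """Write ``<prefix>_vx/vy/vz.nii.gz`` plus ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(field.spacing)
    for name, comp in zip(("vx", "vy", "vz"), field.velocity):
        nib.save(nib.Nifti1Image(comp.astype(np.float32), aff),
                 str(prefix) + f"_{name}.nii.gz")
    meta = {
        "venc_m_per_s": field.venc,
        "dt_ms": field.dt_ms,
        "spacing_mm": list(field.spacing),
        "n_phases": field.n_phases,
    }
    if extra_meta:
        meta.update(extra_meta)
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=1))


def load_velocity_field(prefix: str | Path) -> VelocityField4D:
    prefix = Path(prefix)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    comps = [
        np.asarray(nib.load(str(prefix) + f"_{name}.nii.gz").dataobj, dtype=float)
        for name in ("vx", "vy", "vz")
    ]
    return VelocityField4D(
        np.stack(comps),
        tuple(meta["spacing_mm"]),
        meta["dt_ms"],
        meta["venc_m_per_s"],
    )


def save_mask(mask: LumenMask, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing)),
        str(path),
    )


def load_mask(path: str | Path, spacing=None) -> LumenMask:
    img = nib.load(str(path))
    if spacing is None:
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LumenMask(np.asarray(img.dataobj) > 0, spacing)


def save_cine(cine: CineSeries, prefix: str | Path) -> None:
    """Write ``<prefix>.nii.gz`` (X x Y x 1 x T) plus ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vol = np.transpose(cine.frames, (1, 2, 0))[:, :, None, :]
    aff = _affine((cine.pixel_spacing, cine.pixel_spacing, 1.0))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(prefix) + ".nii.gz")
    meta = {
        "pixel_spacing_mm": cine.pixel_spacing,
        "dt_ms": cine.dt_ms,
        "n_phases": cine.n_phases,
    }
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=1))


def load_cine(prefix: str | Path) -> CineSeries:
    prefix = Path(prefix)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    vol = np.asarray(nib.load(str(prefix) + ".nii.gz").dataobj, dtype=float)
    frames = np.transpose(vol[:, :, 0, :], (2, 0, 1))
    return CineSeries(frames, meta["pixel_spacing_mm"], meta["dt_ms"])


def save_centerline(cl: Centerline, path: str | Path) -> None:
    payload = {
        "points_mm": cl.points.tolist(),
        "arc_length_mm": cl.arc_length.tolist(),
        "tangents": cl.tangents.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_centerline(path: str | Path) -> Centerline:
    payload = json.loads(Path(path).read_text())
    return Centerline(np.asarray(payload["points_mm"]))
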
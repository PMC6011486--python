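"""End-to-end convenience pipeline: velocity field in, PWV out.

Chains the standard stages — phase-unwrap, lumen segmentation,
eddy-current correction, centerline extraction, plane placement, flow
integration and the transit-time fit — with the package defaults.
"""

from __future__ import annotations

import numpy as np

from .datatypes import LumenMask, VelocityField4D
from .flow import PulseWaveModel, PulseWaveResults
from .geometry import extract_centerline, place_planes
from .preprocessing import (
    correct_eddy_currents,
    segment_lumen,
    static_tissue_mask,
    unwrap_velocity,
)

__all__ = ["pwv_pipeline", "default_seeds"]


def default_seeds(mask: LumenMask) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Heuristic start/end seeds: extreme lumen voxels along the longest
    mask axis. Adequate for roughly straight vessels; curved anatomies
    should supply explicit seeds."""
    idx = np.argwhere(mask.mask)
    axis = int(np.argmax(idx.max(axis=0) - idx.min(axis=0)))
    return tuple(idx[np.argmin(idx[:, axis])]), tuple(idx[np.argmax(idx[:, axis])])


def pwv_pipeline(
    field: VelocityField4D,
    start_seed: tuple[int, int, int] | None = None,
    end_seed: tuple[int, int, int] | None = None,
    threshold_fraction: float = 0.2,
    plane_spacing_mm: float = 5.0,
    eddy_correction: bool = True,
    robust: bool = False,
) -> PulseWaveResults:
    """Run the full PWV chain and fit all three arrival methods."""
    field = unwrap_velocity(field)
    mask = segment_lumen(field, threshold_fraction)
    if eddy_correction:
        field, _ = correct_eddy_currents(field, static_tissue_mask(field, mask))
    if start_seed is None or end_seed is None:
        start_seed, end_seed = default_seeds(mask)
    cl = extract_centerline(mask, start_seed, end_seed)
    planes = place_planes(cl, mask, spacing_mm=plane_spacing_mm)
    return PulseWaveModel.from_field(field, planes).fit_all(robust=robust)
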
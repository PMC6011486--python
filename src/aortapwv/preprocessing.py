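"""Velocity-field corrections and lumen segmentation.

Phase-contrast velocities alias into [-venc, venc); residual eddy currents
add a slowly varying spatial offset. Both are corrected before any flow is
integrated, then the lumen is segmented from the temporal-maximum speed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import LumenMask, VelocityField4D

__all__ = [
    "unwrap_velocity",
    "correct_eddy_currents",
    "segment_lumen",
    "static_tissue_mask",
]


def unwrap_velocity(field: VelocityField4D) -> VelocityField4D:
    """Undo phase wraps by temporal-neighbor tracking.

    Phase 0 is anchored to its stored value; each later phase is shifted by
    the multiple of 2*venc that minimizes its jump against the already
    corrected previous phase. Wrap-free data pass through unchanged, which
    also makes the operation idempotent.
    """
    v = field.velocity.copy()
    two_venc = 2.0 * field.venc
    for t in range(1, field.n_phases):
        k = np.round((v[..., t - 1] - v[..., t]) / two_venc)
        v[..., t] += two_venc * k
    return VelocityField4D(v, field.spacing, field.dt_ms, field.venc, field.magnitude)


def static_tissue_mask(field: VelocityField4D, lumen: LumenMask,
                       dilate_voxels: int = 2) -> np.ndarray:
    """Static-tissue region: everything away from the (dilated) lumen."""
    grown = ndimage.binary_dilation(lumen.mask, iterations=dilate_voxels)
    return ~grown


def correct_eddy_currents(
    field: VelocityField4D, static_mask: np.ndarray
) -> tuple[VelocityField4D, np.ndarray]:
    """Subtract a first-order spatial polynomial fitted on static tissue.

    For each component, the temporal-mean velocity over ``static_mask``
    voxels is fitted with ``c0 + cx*x + cy*y + cz*z`` (world mm) by least
    squares and the polynomial is subtracted from every voxel and phase.
    Returns the corrected field and the fitted coefficients, shape (3, 4).
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != field.shape:
        raise ValueError("static mask shape must match the field grid")
    n_static = int(static_mask.sum())
    if n_static < 4:
        raise ValueError(
            f"static mask has {n_static} voxels; need >= 4 to determine the "
            "four polynomial coefficients"
        )
    idx = np.argwhere(static_mask)
    xyz = idx * np.asarray(field.spacing)
    design = np.column_stack([np.ones(len(xyz)), xyz])

    shape = field.shape
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1) * np.asarray(field.spacing)
    full_design = np.concatenate(
        [np.ones(shape + (1,)), world], axis=-1
    )  # (X, Y, Z, 4)

    v = field.velocity.copy()
    coeffs = np.empty((3, 4))
    for c in range(3):
        mean_v = field.velocity[c].mean(axis=-1)
        beta, *_ = np.linalg.lstsq(design, mean_v[static_mask], rcond=None)
        coeffs[c] = beta
        v[c] -= (full_design @ beta)[..., None]
    corrected = VelocityField4D(
        v, field.spacing, field.dt_ms, field.venc, field.magnitude
    )
    return corrected, coeffs


def segment_lumen(
    field: VelocityField4D,
    threshold_fraction: float = 0.2,
    closing_iterations: int = 1,
    seed_point: tuple[int, int, int] | None = None,
) -> LumenMask:
    """Segment the lumen from the temporal-maximum speed map.

    Voxels whose peak speed over the cycle exceeds ``threshold_fraction``
    of the global peak are kept; the largest connected component (or, if a
    ``seed_point`` is given, the component containing it) is retained and
    morphologically closed. Deterministic by construction.
    """
    if not 0 < threshold_fraction:
        raise ValueError("threshold_fraction must be positive")
    peak_speed = field.speed().max(axis=-1)
    level = threshold_fraction * peak_speed.max()
    raw = peak_speed > level
    if not raw.any():
        raise ValueError(
            f"no voxel exceeds {threshold_fraction:.3g} of the maximum speed; "
            "lower the threshold"
        )
    labels, n_labels = ndimage.label(raw)
    if seed_point is not None:
        lab = labels[tuple(seed_point)]
        if lab == 0:
            raise ValueError("seed point lies outside every candidate region")
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        lab = int(np.argmax(counts))
    mask = labels == lab
    if closing_iterations > 0:
        mask = ndimage.binary_closing(mask, iterations=closing_iterations)
        # closing can nick in disconnected crumbs at the border; re-select
        labels2, _ = ndimage.label(mask)
        counts2 = np.bincount(labels2.ravel())
        counts2[0] = 0
        mask = labels2 == int(np.argmax(counts2))
    return LumenMask(mask, field.spacing)
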
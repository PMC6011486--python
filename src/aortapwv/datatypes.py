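"""Core containers shared across the pipeline.

Conventions: velocities in m/s, lengths in mm, times in seconds internally
(acquisition metadata keeps its native units, e.g. ``dt_ms``). Voxel indices
are 0-based and world coordinates are ``index * spacing`` — no affine beyond
anisotropic scaling is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VelocityField4D",
    "LumenMask",
    "Centerline",
    "AnalysisPlane",
    "FlowWaveform",
    "ArrivalTimes",
    "PWVEstimate",
    "CineSeries",
    "Contour",
    "DiameterCurve",
    "BloodPressure",
    "DCResult",
]


@dataclass
class VelocityField4D:
    """Time-resolved three-directional velocity data on a regular grid.

    Parameters
    ----------
    velocity : ndarray, shape (3, X, Y, Z, T)
        Velocity components (vx, vy, vz) in m/s.
    spacing : sequence of 3 floats
        Voxel spacing in mm.
    dt_ms : float
        Temporal resolution (phase spacing) in milliseconds.
    venc : float
        Velocity encoding sensitivity in m/s; stored phases alias into
        ``[-venc, venc)``.
    magnitude : ndarray, optional
        Anatomical magnitude image, shape (X, Y, Z) or (X, Y, Z, T).
    """

    velocity: np.ndarray
    spacing: tuple[float, float, float]
    dt_ms: float
    venc: float
    magnitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 5 or self.velocity.shape[0] != 3:
            raise ValueError(
                f"velocity must have shape (3, X, Y, Z, T), got {self.velocity.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.n_phases < 2:
            raise ValueError("need at least 2 cardiac phases")
        if self.venc <= 0:
            raise ValueError("venc must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[1:4]

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[-1]

    @property
    def times(self) -> np.ndarray:
        """Phase times in seconds, starting at 0."""
        return np.arange(self.n_phases) * self.dt_ms / 1000.0

    def speed(self) -> np.ndarray:
        """Voxelwise velocity magnitude, shape (X, Y, Z, T)."""
        return np.sqrt(np.sum(self.velocity**2, axis=0))

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            self.velocity.copy(),
            self.spacing,
            self.dt_ms,
            self.venc,
            None if self.magnitude is None else self.magnitude.copy(),
        )


@dataclass
class LumenMask:
    """Static boolean segmentation of the aortic lumen."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def world_coords(self) -> np.ndarray:
        """World coordinates (mm) of all mask voxels, shape (N, 3)."""
        idx = np.argwhere(self.mask)
        return idx * np.asarray(self.spacing)


class Centerline:
    """Ordered vessel centerline with arc-length parameterization.

    Points are world coordinates in mm. Arc length ``s`` starts at 0 at the
    first point; tangents are unit vectors obtained by central differences.
    """

    def __init__(self, points: np.ndarray):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
            raise ValueError("centerline needs at least 2 points of shape (N, 3)")
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline points must be strictly ordered (no repeats)")
        self.points = points
        self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        tang = np.gradient(points, self.arc_length, axis=0)
        norms = np.linalg.norm(tang, axis=1, keepdims=True)
        self.tangents = tang / norms

    @property
    def length(self) -> float:
        """Total arc length in mm."""
        return float(self.arc_length[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Interpolated point(s) at arc length ``s`` (mm)."""
        s = np.asarray(s, dtype=float)
        out = np.stack(
            [np.interp(s, self.arc_length, self.points[:, i]) for i in range(3)],
            axis=-1,
        )
        return out

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        """Interpolated unit tangent(s) at arc length ``s`` (mm)."""
        s = np.asarray(s, dtype=float)
        t = np.stack(
            [np.interp(s, self.arc_length, self.tangents[:, i]) for i in range(3)],
            axis=-1,
        )
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def resample(self, spacing: float = 1.0) -> "Centerline":
        """Return a copy resampled to uniform arc-length spacing (mm)."""
        n = max(2, int(round(self.length / spacing)) + 1)
        s = np.linspace(0.0, self.length, n)
        return Centerline(self.point_at(s))


@dataclass
class AnalysisPlane:
    """A cross-sectional analysis plane normal to the centerline.

    The in-plane grid is square with ``grid_shape`` cells of size
    ``grid_spacing`` mm; ``lumen`` flags grid cells inside the vessel.
    """

    center: np.ndarray
    normal: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray
    s_mm: float
    grid_spacing: float
    lumen: np.ndarray
    plane_id: int = 0

    def __post_init__(self) -> None:
        for name in ("center", "normal", "basis_u", "basis_v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(self.normal @ self.basis_u) > 1e-6 or abs(self.normal @ self.basis_v) > 1e-6:
            raise ValueError("plane basis vectors must be orthogonal to the normal")
        self.lumen = np.asarray(self.lumen, dtype=bool)

    def world_coords(self) -> np.ndarray:
        """World coordinates of every grid cell center, shape (H, W, 3)."""
        h, w = self.lumen.shape
        iu = (np.arange(h) - (h - 1) / 2.0) * self.grid_spacing
        iv = (np.arange(w) - (w - 1) / 2.0) * self.grid_spacing
        uu, vv = np.meshgrid(iu, iv, indexing="ij")
        return (
            self.center[None, None, :]
            + uu[..., None] * self.basis_u[None, None, :]
            + vv[..., None] * self.basis_v[None, None, :]
        )

    @property
    def lumen_area_mm2(self) -> float:
        return float(self.lumen.sum()) * self.grid_spacing**2


@dataclass
class FlowWaveform:
    """Through-plane flow rate vs time at one analysis plane."""

    plane_id: int
    s_mm: float
    times: np.ndarray  # s, uniform grid
    flow: np.ndarray  # mL/s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.times.shape != self.flow.shape:
            raise ValueError("times and flow must have equal length")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("waveform requires a uniform time grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ArrivalTimes:
    """Per-plane wave-arrival metric for one detection method.

    For cross-correlation, ``tau`` holds lags relative to the reference
    (most proximal) plane; for TTF / half-peak it holds absolute arrival
    times.  Either way the transit-time slope vs ``s_mm`` is 1/PWV.
    """

    method: str
    s_mm: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.s_mm = np.asarray(self.s_mm, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.s_mm.shape != self.tau.shape:
            raise ValueError("s_mm and tau must align")


@dataclass
class PWVEstimate:
    """Pulse wave velocity from the linear transit-time fit."""

    pwv: float  # m/s
    slope: float  # s/mm
    intercept: float  # s
    r_squared: float
    n_planes: int
    method: str
    valid: bool = True
    regression: str = "tau_on_distance"


@dataclass
class CineSeries:
    """2D CINE image series: one slice through the cardiac cycle."""

    frames: np.ndarray  # (n_phases, H, W)
    pixel_spacing: float  # mm
    dt_ms: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_phases, H, W)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 cardiac phases")

    @property
    def n_phases(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


class Contour:
    """Closed vessel contour on one CINE frame, stored as a polygon.

    Vertices are (row, col) pixel coordinates. Area uses the shoelace
    formula, so sub-pixel boundary positions are respected.
    """

    def __init__(self, frame_index: int, polygon: np.ndarray):
        polygon = np.asarray(polygon, dtype=float)
        if polygon.ndim != 2 or polygon.shape[1] != 2 or len(polygon) < 3:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        self.frame_index = int(frame_index)
        self.polygon = polygon
        if self.area_px <= 0:
            raise ValueError("contour encloses no area")

    @property
    def area_px(self) -> float:
        """Enclosed area in pixel^2 (shoelace)."""
        y, x = self.polygon[:, 0], self.polygon[:, 1]
        return float(abs(np.dot(y, np.roll(x, -1)) - np.dot(x, np.roll(y, -1))) / 2.0)

    @classmethod
    def from_mask(cls, frame_index: int, mask: np.ndarray) -> "Contour":
        """Build a polygon contour from a binary region (0.5 iso-level)."""
        from skimage import measure

        mask = np.asarray(mask, dtype=float)
        contours = measure.find_contours(mask, 0.5)
        if not contours:
            raise ValueError("mask contains no region")
        poly = max(contours, key=len)
        return cls(frame_index, poly)

    @classmethod
    def circle(cls, frame_index: int, center: Sequence[float], radius_px: float,
               n_vertices: int = 128) -> "Contour":
        theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        pts = np.stack(
            [center[0] + radius_px * np.sin(theta), center[1] + radius_px * np.cos(theta)],
            axis=1,
        )
        return cls(frame_index, pts)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        from skimage.draw import polygon as draw_polygon

        rr, cc = draw_polygon(self.polygon[:, 0], self.polygon[:, 1], shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask


@dataclass
class DiameterCurve:
    """Per-phase circular-equivalent diameter of a vessel cross-section."""

    diameters_mm: np.ndarray
    end_diastolic_frame: int

    def __post_init__(self) -> None:
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=float)

    @property
    def dd_mm(self) -> float:
        """End-diastolic diameter Dd (mm)."""
        return float(self.diameters_mm[self.end_diastolic_frame])

    @property
    def delta_d_mm(self) -> float:
        """Systolic diameter excursion max(d) - Dd (mm)."""
        return float(self.diameters_mm.max() - self.dd_mm)


MMHG_TO_KPA = 0.133322


@dataclass
class BloodPressure:
    """Brachial pressures in mmHg (each the pre/post-scan average)."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not (self.systolic > self.diastolic > 0):
            raise ValueError("require systolic > diastolic > 0")

    @property
    def pulse_pressure_mmhg(self) -> float:
        return float(self.systolic - self.diastolic)

    @property
    def pulse_pressure_kpa(self) -> float:
        return self.pulse_pressure_mmhg * MMHG_TO_KPA


@dataclass
class DCResult:
    """Distensibility coefficient with its inputs echoed."""

    dc: float  # 1e-3 / kPa
    site: str
    delta_d_mm: float
    dd_mm: float
    pulse_pressure_mmhg: float
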
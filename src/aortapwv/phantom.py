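"""Digital phantoms with analytic ground truth.

Three generators cover the pipeline's inputs:

* a 4D flow phantom — a candy-cane tube (straight ascending segment,
  semicircular arch, straight descending segment) carrying a systolic flow
  pulse that propagates along the centerline at a prescribed pulse wave
  velocity, rendered onto a velocity grid at MRI-like resolution
  (2.5 x 2.1 x 2.5 mm voxels, 20 ms phases, venc 1.5 m/s by default);
* a 2D CINE phantom — a pulsating disk with a known per-phase diameter;
* a cohort simulator — subject tables drawn from an age+sex linear
  reference model for PWV, with plausible covariate links.

Every generator returns the ground truth alongside the data and is
deterministic under its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .datatypes import Centerline, CineSeries, DiameterCurve, LumenMask, VelocityField4D

__all__ = [
    "PhantomSpec",
    "CinePhantomSpec",
    "CohortSpec",
    "TABLE3_CELL_SIZES",
    "candy_cane_centerline",
    "systolic_waveform",
    "wrap_to_venc",
    "make_flow_phantom",
    "make_cine_phantom",
    "simulate_cohort",
]


def wrap_to_venc(v: np.ndarray, venc: float) -> np.ndarray:
    """Alias velocities into [-venc, venc) as phase-contrast encoding does."""
    return np.mod(v + venc, 2.0 * venc) - venc


def candy_cane_centerline(
    ascending_mm: float = 90.0,
    arch_radius_mm: float = 35.0,
    descending_mm: float = 101.0,
    step_mm: float = 0.5,
    origin: np.ndarray | None = None,
) -> Centerline:
    """Analytic thoracic-aorta-like centerline in the x-z plane.

    Runs upward (+z) for ``ascending_mm``, over a semicircular arch of
    radius ``arch_radius_mm``, then downward (-z) for ``descending_mm``.
    Total arc length = ascending + pi*R + descending (~300 mm by default).
    """
    if min(ascending_mm, arch_radius_mm, descending_mm) <= 0:
        raise ValueError("all geometry lengths must be positive")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    r = arch_radius_mm
    s_total = ascending_mm + np.pi * r + descending_mm
    s = np.arange(0.0, s_total + step_mm / 2, step_mm)
    pts = np.empty((len(s), 3))
    # ascending limb
    m1 = s <= ascending_mm
    pts[m1] = origin + np.outer(s[m1], [0.0, 0.0, 1.0])
    # arch: semicircle from (0,0,asc) to (2R,0,asc), apex at z = asc + R
    m2 = (s > ascending_mm) & (s <= ascending_mm + np.pi * r)
    theta = (s[m2] - ascending_mm) / r
    pts[m2, 0] = origin[0] + r * (1 - np.cos(theta))
    pts[m2, 1] = origin[1]
    pts[m2, 2] = origin[2] + ascending_mm + r * np.sin(theta)
    # descending limb
    m3 = s > ascending_mm + np.pi * r
    pts[m3, 0] = origin[0] + 2 * r
    pts[m3, 1] = origin[1]
    pts[m3, 2] = origin[2] + ascending_mm - (s[m3] - ascending_mm - np.pi * r)
    return Centerline(pts)


def systolic_waveform(
    t: np.ndarray,
    onset_s: float,
    upstroke_s: float,
    downstroke_s: float,
    peak: float,
) -> np.ndarray:
    """Raised-cosine systolic pulse over a flat zero diastolic baseline.

    The pulse rises from the baseline at ``onset_s`` over ``upstroke_s``
    and relaxes back over ``downstroke_s``; this leaves an unambiguous
    foot, half-peak crossing and correlation peak for all three arrival
    detectors.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    up = (t >= onset_s) & (t < onset_s + upstroke_s)
    out[up] = 0.5 * peak * (1 - np.cos(np.pi * (t[up] - onset_s) / upstroke_s))
    t_peak = onset_s + upstroke_s
    down = (t >= t_peak) & (t < t_peak + downstroke_s)
    out[down] = 0.5 * peak * (1 + np.cos(np.pi * (t[down] - t_peak) / downstroke_s))
    return out


@dataclass
class PhantomSpec:
    """Parameters of the 4D flow phantom.

    Geometry lengths in mm, velocities in m/s, ``dt_ms`` in ms. The eddy
    coefficients, when given, are per-component first-order spatial
    polynomials ``(c0, cx, cy, cz)`` added to the stored velocities
    (units m/s and m/s per mm).
    """

    ascending_mm: float = 90.0
    arch_radius_mm: float = 35.0
    descending_mm: float = 101.0
    lumen_radius_mm: float = 12.0
    true_pwv: float = 5.0
    onset_s: float = 0.06
    upstroke_s: float = 0.10
    downstroke_s: float = 0.18
    peak_velocity: float = 1.0
    profile: str = "plug"  # or "parabolic"
    spacing_mm: tuple[float, float, float] = (2.5, 2.1, 2.5)
    dt_ms: float = 20.0
    n_phases: int = 40
    venc: float = 1.5
    noise_sd: float = 0.0
    eddy_coeffs: np.ndarray | None = None  # (3, 4): c0, cx, cy, cz per comp.
    wrap_enabled: bool = False
    margin_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_pwv <= 0:
            raise ValueError("true_pwv must be positive")
        if self.lumen_radius_mm < 2 * max(self.spacing_mm):
            raise ValueError(
                "lumen radius must be >= 2x the largest voxel spacing to be "
                f"resolvable (radius {self.lumen_radius_mm} mm, spacing "
                f"{max(self.spacing_mm)} mm)"
            )
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.profile not in ("plug", "parabolic"):
            raise ValueError("profile must be 'plug' or 'parabolic'")

    @property
    def centerline_length_mm(self) -> float:
        return self.ascending_mm + np.pi * self.arch_radius_mm + self.descending_mm


def make_flow_phantom(
    spec: PhantomSpec,
) -> tuple[VelocityField4D, Centerline, LumenMask]:
    """Render the flow phantom; returns (field, true centerline, true mask).

    Through-lumen velocity at arc length ``s`` and time ``t`` equals
    ``profile(r) * waveform(t - s / true_pwv)`` directed along the local
    tangent; outside the lumen velocity is zero plus the requested
    artifacts (eddy offsets, noise, wrapping).
    """
    rng = np.random.default_rng(spec.seed)
    max_delay = spec.centerline_length_mm / (spec.true_pwv * 1000.0)
    duration = spec.n_phases * spec.dt_ms / 1000.0
    pulse_end = spec.onset_s + spec.upstroke_s + spec.downstroke_s
    if duration < pulse_end + max_delay:
        warnings.warn(
            "acquisition window shorter than pulse duration plus maximal "
            "transit delay; the wave never fully arrives distally",
            stacklevel=2,
        )

    margin = spec.margin_mm
    origin = np.array([margin, margin, margin + spec.descending_mm - spec.ascending_mm])
    origin[2] = max(origin[2], margin)
    cl = candy_cane_centerline(
        spec.ascending_mm, spec.arch_radius_mm, spec.descending_mm, origin=origin
    )

    lo = cl.points.min(axis=0) - margin
    hi = cl.points.max(axis=0) + margin
    if np.any(lo < 0):  # shift so the grid starts at world 0
        cl = Centerline(cl.points - lo)
        hi = hi - lo
    spacing = np.asarray(spec.spacing_mm)
    shape = tuple(int(np.ceil(h / sp)) + 1 for h, sp in zip(hi, spacing))

    # distance/arc-length lookup against a dense analytic centerline
    tree = cKDTree(cl.points)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spacing
    dist, idx = tree.query(coords, workers=-1)
    mask = (dist <= spec.lumen_radius_mm).reshape(shape)

    # velocities carry a one-voxel linear partial-volume rim, as scanner
    # voxel averaging would produce; without it the rasterized flux through
    # a plane is lumpy at coarse MRI resolution
    pv_width = float(np.mean(spacing))
    pv = np.clip((spec.lumen_radius_mm - dist) / pv_width + 0.5, 0.0, 1.0)
    lumen_flat = pv > 0.0

    velocity = np.zeros((3,) + shape + (spec.n_phases,))
    times = np.arange(spec.n_phases) * spec.dt_ms / 1000.0
    s_vox = cl.arc_length[idx[lumen_flat]]  # mm
    tangents = cl.tangents[idx[lumen_flat]]  # (N, 3)
    delays = s_vox / (spec.true_pwv * 1000.0)  # s
    amp = pv[lumen_flat]
    if spec.profile == "parabolic":
        amp = amp * np.clip(
            1.0 - (dist[lumen_flat] / spec.lumen_radius_mm) ** 2, 0.0, None
        )
    wav = systolic_waveform(
        times[None, :] - delays[:, None],
        spec.onset_s,
        spec.upstroke_s,
        spec.downstroke_s,
        spec.peak_velocity,
    )  # (N, T)
    v_lumen = amp[:, None, None] * wav[:, None, :] * tangents[:, :, None]  # (N, 3, T)
    flat_idx = np.flatnonzero(lumen_flat)
    vox = np.unravel_index(flat_idx, shape)
    for c in range(3):
        velocity[c][vox] = v_lumen[:, c, :]

    if spec.eddy_coeffs is not None:
        coef = np.asarray(spec.eddy_coeffs, dtype=float)
        if coef.shape != (3, 4):
            raise ValueError("eddy_coeffs must have shape (3, 4)")
        xyz = coords.reshape(shape + (3,))
        for c in range(3):
            offset = coef[c, 0] + xyz @ coef[c, 1:]
            velocity[c] += offset[..., None]

    if spec.noise_sd > 0:
        velocity += rng.normal(0.0, spec.noise_sd, size=velocity.shape)

    if spec.wrap_enabled:
        velocity = wrap_to_venc(velocity, spec.venc)

    field = VelocityField4D(velocity, tuple(spacing), spec.dt_ms, spec.venc)
    return field, cl, LumenMask(mask, tuple(spacing))


# ---------------------------------------------------------------------------
# 2D CINE phantom


@dataclass
class CinePhantomSpec:
    """A pulsating-disk CINE phantom (vessel cross-section through the cycle)."""

    dd_mm: float = 24.0
    delta_d_mm: float = 2.0
    n_phases: int = 25
    pixel_spacing_mm: float = 1.8
    image_size: tuple[int, int] = (64, 64)
    systolic_frame: int = 8
    vessel_intensity: float = 1.0
    background_intensity: float = 0.15
    blur_sd_px: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_d_mm < 0:
            raise ValueError("diameter excursion must be >= 0")
        if self.dd_mm <= self.delta_d_mm:
            raise ValueError("end-diastolic diameter must exceed the excursion")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if not (0 < self.systolic_frame < self.n_phases):
            raise ValueError("systolic_frame must lie inside the cycle")

    def pulsation(self) -> np.ndarray:
        """Normalized diameter waveform w_k in [0, 1] with w_0 = 0."""
        k = np.arange(self.n_phases)
        w = np.zeros(self.n_phases)
        up = k <= self.systolic_frame
        w[up] = 0.5 * (1 - np.cos(np.pi * k[up] / self.systolic_frame))
        n_down = self.n_phases - 1 - self.systolic_frame
        down = ~up
        w[down] = 0.5 * (1 + np.cos(np.pi * (k[down] - self.systolic_frame) / n_down))
        return w


def make_cine_phantom(spec: CinePhantomSpec) -> tuple[CineSeries, DiameterCurve]:
    """Render the CINE phantom; returns (series, true diameter curve).

    Frame ``k`` depicts an anti-aliased disk of diameter
    ``Dd + delta_d * w_k`` centered in the image; the returned curve lists
    those diameters exactly, with frame 0 as the end-diastolic frame.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.pulsation()
    d_mm = spec.dd_mm + spec.delta_d_mm * w
    r_px = d_mm / 2.0 / spec.pixel_spacing_mm
    h, wdt = spec.image_size
    cy, cx = (h - 1) / 2.0, (wdt - 1) / 2.0
    pad = 2.0 + 3 * spec.blur_sd_px
    if r_px.max() + pad > min(cy, cx, h - 1 - cy, wdt - 1 - cx):
        raise ValueError("disk (plus blur margin) exceeds the image bounds")

    yy, xx = np.meshgrid(np.arange(h), np.arange(wdt), indexing="ij")
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    frames = np.empty((spec.n_phases, h, wdt))
    lo, hi = spec.background_intensity, spec.vessel_intensity
    for k in range(spec.n_phases):
        edge = np.clip(r_px[k] - rr + 0.5, 0.0, 1.0)  # 1-px anti-aliased rim
        img = lo + (hi - lo) * edge
        if spec.blur_sd_px > 0:
            img = gaussian_filter(img, spec.blur_sd_px)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[k] = img

    series = CineSeries(frames, spec.pixel_spacing_mm, dt_ms=40.0)
    truth = DiameterCurve(d_mm, end_diastolic_frame=0)
    return series, truth


# ---------------------------------------------------------------------------
# cohort simulator

#: (sex, decade-start) -> cell size of the reference population (n = 126).
TABLE3_CELL_SIZES: dict[tuple[str, int], int] = {
    ("female", 20): 10, ("female", 30): 9, ("female", 40): 11,
    ("female", 50): 13, ("female", 60): 12, ("female", 70): 9,
    ("male", 20): 10, ("male", 30): 14, ("male", 40): 10,
    ("male", 50): 10, ("male", 60): 9, ("male", 70): 9,
}


@dataclass
class CohortSpec:
    """Simulation settings for a subject cohort.

    PWV follows the linear reference model
    ``PWV = beta0 + beta_age * age + beta_male * male + N(0, sigma)``
    with ages uniform within each decade cell. ``method_scatter`` adds
    independent noise to the TTF / half-peak columns on top of the
    cross-correlation value, emulating algorithm-level disagreement.
    When ``covariates`` is true, blood pressures, aortic diameters and
    distensibility are generated with age links of realistic sign and
    size (DC decays with age while PWV rises).
    """

    cell_sizes: dict[tuple[str, int], int] = field(
        default_factory=lambda: dict(TABLE3_CELL_SIZES)
    )
    beta0: float = 1.51
    beta_age: float = 0.080
    beta_male: float = 0.53
    sigma: float = 0.77
    method_scatter: float = 0.15
    covariates: bool = True
    age_sex_interaction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("residual sd must be >= 0")
        if any(n < 0 for n in self.cell_sizes.values()):
            raise ValueError("cell sizes must be >= 0")
        if sum(self.cell_sizes.values()) <= 0:
            raise ValueError("total cohort size must be positive")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from the reference model.

    Returns a DataFrame with one row per subject: ``id, age, sex, male,
    pwv_xcor, pwv_ttf, pwv_half_peak`` and, when requested, blood
    pressures (mmHg), heart rate (bpm), aortic diameters (mm),
    distensibility (1e-3/kPa), BMI and plaque thickness.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for (sex, decade), n in sorted(spec.cell_sizes.items()):
        male = 1 if sex == "male" else 0
        ages = rng.uniform(decade, decade + 10, size=n)
        mu = (
            spec.beta0
            + spec.beta_age * ages
            + spec.beta_male * male
            + spec.age_sex_interaction * ages * male
        )
        pwv = mu + rng.normal(0.0, spec.sigma, size=n)
        for a, p in zip(ages, pwv):
            rows.append({"age": a, "sex": sex, "male": male, "pwv_xcor": p})
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"S{i:04d}" for i in range(len(df))])
    n = len(df)
    df["pwv_ttf"] = df["pwv_xcor"] + rng.normal(0.0, spec.method_scatter, n)
    df["pwv_half_peak"] = df["pwv_xcor"] + rng.normal(0.0, spec.method_scatter, n)

    if spec.covariates:
        age = df["age"].to_numpy()
        male = df["male"].to_numpy()
        sbp = 110 + 0.35 * age + rng.normal(0, 8, n)
        dbp = 68 + 0.20 * age + rng.normal(0, 6, n)
        dbp = np.minimum(dbp, sbp - 20)  # keep a physiological pulse pressure
        df["sbp_pre"] = sbp + rng.normal(0, 4, n)
        df["sbp_post"] = sbp + rng.normal(0, 4, n)
        df["dbp_pre"] = dbp + rng.normal(0, 3, n)
        df["dbp_post"] = dbp + rng.normal(0, 3, n)
        df["heart_rate"] = rng.normal(66, 8, n)
        df["dc_aao"] = np.clip(8.5 - 0.09 * age + rng.normal(0, 0.7, n), 0.3, None)
        df["dc_dao"] = np.clip(9.5 - 0.085 * age + rng.normal(0, 0.7, n), 0.3, None)
        df["diam_aao"] = 26 + 0.10 * age + 2.0 * male + rng.normal(0, 2.5, n)
        df["diam_arch"] = 24 + 0.08 * age + 1.5 * male + rng.normal(0, 2.0, n)
        df["diam_dao"] = 20 + 0.07 * age + 1.5 * male + rng.normal(0, 2.0, n)
        df["bmi"] = np.clip(rng.normal(24.8, 4.1, n), 16, None)
        df["plaque_thickness"] = np.clip(
            rng.normal(0.03 * np.maximum(age - 40, 0), 0.5), 0, None
        )
    return df
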
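# Methods

This note documents the models, numerical choices and limitations of the
package. Units throughout: velocities in m/s, lengths in mm, times in
seconds (acquisition metadata keeps native units such as `dt_ms`). Voxel
indices are 0-based; world coordinates are `index × spacing`.

## 1. Flow phantom

The 4D flow phantom is a "candy-cane" tube: a straight ascending limb
(90 mm), a semicircular arch (radius 35 mm, arc ≈ 110 mm) and a straight
descending limb (101 mm), ≈ 301 mm of centerline in total — the length
of a thoracic aorta. The lumen is a tube of radius 12 mm around this
centerline. Velocity at arc length *s* and time *t* is

    v(s, r, t) = profile(r) · w(t − s / PWV) · t̂(s)

with `w` a raised-cosine systolic pulse (onset 0.06 s, upstroke 0.10 s,
downstroke 0.18 s, peak 1 m/s over a flat zero diastolic baseline) and
`t̂` the local tangent. The raised cosine gives every arrival detector a
well-defined foot, half-peak crossing and correlation peak. The profile
is plug (default) or parabolic. The grid defaults mirror a typical 3 T
protocol: 2.5 × 2.1 × 2.5 mm voxels, 20 ms phases (40 phases ≈ 0.8 s,
enough for the pulse plus the distal transit delay), venc 1.5 m/s.

Rasterization uses a one-voxel linear **partial-volume rim**: voxels
whose center lies within half a mean-voxel of the wall carry linearly
attenuated velocity. This emulates scanner voxel averaging; with a hard
rim the flux through an analysis plane is lumpy at this resolution (up
to −9% at 10 mm lumen radius purely from lattice effects). With the rim,
plane-integrated flow matches `area × centerline velocity` to ~1–2%; the
residual is trilinear through-plane sampling, which mixes adjacent
slices and smears ≈ 0.5 ms of transit timing onto the upstroke.

Optional artifacts: Gaussian velocity noise; a per-component first-order
eddy-current polynomial `c₀ + cₓx + c_y y + c_z z`; and venc wrapping,
`stored = ((v + venc) mod 2·venc) − venc`. Everything is reproducible
under the spec's seed. The generator only claims *algorithmic* fidelity:
real subjects' waveform shapes, reflected waves, turbulence and
respiratory motion are not modeled, so passing tests demonstrate
correctness of the estimators, not clinical accuracy on patient data.

## 2. Preprocessing

**Unwrapping** is temporal-neighbor based: phase 0 anchors; each later
phase adds the multiple of 2·venc minimizing the jump against the
corrected previous phase. This matches the dominant aliasing mode of
velocity-encoded data, is exactly testable on the phantom, and is
idempotent on wrap-free data. Spatial region-growing unwrapping is out
of scope.

**Eddy-current correction** fits a first-order spatial polynomial (4
coefficients per component) to the temporal-mean velocity of static
tissue — everything outside a 2-voxel dilation of the lumen — by least
squares and subtracts it everywhere. First order is the minimal standard
model; the correction is linear in the injected offset, and fewer than 4
static voxels is rejected.

**Segmentation** thresholds the temporal-maximum speed map at a fraction
(default 0.2) of its global maximum, keeps the largest connected
component (or the component containing an optional seed point — the
reproducible stand-in for an interactive step), and closes
morphologically. Monotone in the threshold and deterministic.

## 3. Centerline and planes

The centerline is a minimum-cost path between two user seed voxels with
cost `1/(EDT + 0.5)` inside the mask (EDT = Euclidean distance to the
wall, computed with anisotropic sampling), so the path hugs the vessel
axis. The raw voxel path overestimates arc length ≈ 2% through zig-zag;
a cubic smoothing spline with factor `0.25 · N · mean(spacing)²`
restores the analytic length of the candy-cane to 0.1% without cutting
the arch corner (larger factors shortcut the bend and bias PWV high).
The result is resampled to uniform 1 mm arc length; tangents by central
differences.

Planes sit at `s = s_start, s_start + 5 mm, … ≤ s_end`
(count = ⌊L/spacing⌋ + 1, reproducing 61 planes on 300 mm; whether the
count includes both endpoints is otherwise unobservable, and this
convention is adopted). Each plane's normal is the local tangent; the
in-plane square grid has side 4 × the estimated lumen radius at the
smallest voxel spacing, samples the mask trilinearly and keeps the
connected cross-section containing the centerline point. A spacing
longer than the segment yields one plane plus a warning — the PWV fit
then fails loudly downstream rather than fabricating geometry.
Distances for PWV are **arc lengths**, not chords.

## 4. Flow waveforms and PWV

Through-plane flow is `Q = Σ (v·n̂) · cell area` over the cross-section
dilated by one cell (to capture the partial-volume rim), sampled
trilinearly; v in m/s times mm² gives mL/s directly.

Arrival detectors, per waveform:

* **TTF** — the upstroke runs from the last pre-peak sample near the
  baseline to the global peak; baseline = median of all earlier samples;
  a least-squares line through the exact 20% and 80% crossings plus the
  samples between them is intersected with the baseline.
* **Half-peak** — first upstroke crossing of baseline + 0.5·(peak −
  baseline), linearly interpolated.
* **Cross-correlation** — normalized correlation against the most
  proximal plane after subtracting each waveform's *median* (the
  diastolic baseline). Subtracting the mean instead makes diastole
  negative and the zero-padded lag tails drag the peak toward zero
  (−3 ms systematic on a 20 ms grid — measured). The integer-lag peak
  is refined by a cubic spline over ±4 lags evaluated on a 1/200-sample
  grid; a plain 3-point parabola pulls sub-sample lags toward integers.

All three are invariant to amplitude scaling and equivariant to time
shifts. PWV comes from OLS of τ on s; slope ≤ 0 flags the estimate
invalid instead of reporting a negative velocity. τ is regressed on
distance (not the reverse) because distance is the low-noise variable;
the orientation is recorded in the result. An optional robust mode drops
residuals beyond 3 MAD and refits once — off by default, since no
outlier-handling protocol is prescribed for the slope fit. The default
method for cohort work is cross-correlation (fewest outliers in
practice). `PulseWaveModel.fit()/.fit_all()` return a results object
with estimates, R², per-plane arrivals, `summary()` and `plot()`.

On noiseless phantoms all three detectors agree within 3% and recover
the generating PWV within 2%; at 5% velocity noise the 20-seed mean bias
stays below 5%; halving the temporal resolution to 10 ms moves the
noiseless estimate by < 1% — the many-plane fit compensates coarse
temporal sampling.

## 5. CINE tracking and distensibility

The CINE phantom renders an anti-aliased disk whose diameter follows
`Dd + Δd·w_k` with a raised-cosine pulsation (frame 0 end-diastolic,
systole at frame 8 of 25).

Contours are polygons; areas use the shoelace formula times spacing², so
sub-pixel boundary motion is respected (integer pixel counting at 1.8 mm
pixels quantizes area too coarsely to resolve a 1–2 mm excursion; a
pixel-summation path exists for mask-based contours via
`Contour.to_mask`).

The frame-to-frame displacement field is a fixed-schedule, multi-scale
phase-based registration in the Morphon family: complex Gabor quadrature
filters along each axis (wavelengths 8 and 6 px, σ = λ/2, with a
transverse Gaussian window of σ = λ/2 for orientation selectivity),
3 iterations per scale. Per iteration the phase difference between the
fixed and warped-moving responses gives a level-set shift per axis;
because a 1-D filter only observes motion along the structure normal,
the axis observations are projected onto the local gradient direction
and combined by certainty-weighted least squares (certainty = response
magnitude × squared alignment). Without this projection each axis
measures `δ/cos θ` and advecting both components double-counts the
motion (a +20–30% excursion overestimate, measured on disk phantoms).
The warp uses cubic interpolation: linear warps blur the edge enough to
bias the converged sub-pixel displacement. The update field is smoothed
(σ = 0.75 λ) with normalized certainty weighting and accumulated; the
schedule is fixed, so results are deterministic.

Contours propagate serially from the reference frame (forward then
backward), each field advecting the polygon vertices. Equivalent
diameter is `2·√(A/π)`; the end-diastolic frame defaults to the minimum
diameter (the spec of "end-diastolic" without a named frame), and is
configurable. DC uses the fixed bridge 1 mmHg = 0.133322 kPa and is
reported in 10⁻³/kPa.

**Validated range**: on phantom grids with Dd ≥ 24 mm at 1.8 mm pixels
(lumen radius ≥ ~6.7 px) the recovered DC is within 5% of the analytic
value. Below ~6.5 px radius a grid-phase-dependent bias of the sub-pixel
tracker exceeds that (≈ −12% at Dd = 22 mm); tracking smaller vessels
needs finer pixels, and results there should not be trusted to 5%.

## 6. Cohort statistics

* **Reference model**: OLS of PWV on age and a male indicator
  (male = 1, female = 0) via statsmodels; σ = √(SSR/(n−3)); the age×sex
  interaction p-value comes from an augmented fit. Single-sex cohorts are
  rejected (the male coefficient is inestimable).
* **Adjusted correlation**: each variable residualized on age + sex,
  Pearson r between residuals. With no covariates this is exactly plain
  Pearson. The p-value uses n − 2 df on the residual vectors and is
  therefore slightly anti-conservative in the adjusted case — documented
  as approximate. No multiplicity correction by default.
* **Bland–Altman**: differences obs2 − obs1; sd with the n−1
  denominator; limits of agreement mean ± 1.96·sd; plot payload included.
* **Wilcoxon**: paired signed-rank (the three PWV algorithms are
  computed on the same subjects, so pairing is inherent); exact null for
  ≤ 25 non-zero differences (verified against full sign-flip
  enumeration), normal approximation with continuity correction above;
  zero differences dropped; all-zero input rejected.

The cohort simulator draws ages uniformly within each decade-by-sex cell
(default cell sizes sum to n = 126, matching the reference population),
PWV from the linear model, and — when enabled — covariates with
realistic signs and magnitudes: blood pressure rising with age,
distensibility falling ≈ 0.09 × 10⁻³/kPa per year (so PWV and DC
correlate negatively, as physiology dictates), aortic diameters growing
with age and male sex. These links are illustrative defaults for
integration tests, not fitted population parameters.

## 7. Problem sizes and runtimes

Defaults keep every stage desk-scale: the full-size flow phantom is
≈ 45 × 22 × 68 voxels × 40 phases and runs the complete PWV pipeline in
under a second; the acceptance suite (noiseless recovery, 20 noisy
seeds, a DC grid, 200 cohort replicates) completes in well under a
minute. The acceptance script simulates 200 × 126 subjects and runs in
seconds.

## 8. Known limitations

* No k-space/MRI physics: phantoms are generated in image space, since
  the estimators consume reconstructed velocities.
* The lumen mask is static over the cycle; vessel wall motion in the
  4D flow data is not modeled (it is modeled in the CINE phantom, where
  it is the signal).
* Branch vessels, wave reflections and turbulence are absent; local
  (per-segment) PWV is out of scope — it would need ≪ 10 ms temporal
  resolution.
* The CINE tracker's sub-pixel accuracy degrades below ~6.5 px lumen
  radius (see §5).
* Centerline seeds are manual by design (mirroring the interactive
  workflow); the heuristic auto-seeding in the CLI assumes a roughly
  straight vessel and should not be used for the candy-cane geometry
  without explicit seeds.
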
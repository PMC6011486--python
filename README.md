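# aortapwv

Aortic stiffness from 4D flow MRI: pulse wave velocity, distensibility,
and reference-value statistics — with digital phantoms that make every
stage testable against known ground truth.

## The problem

Aortic stiffening is an early, independent marker of cardiovascular risk.
Two imaging biomarkers quantify it:

* **Pulse wave velocity (PWV)** — the speed at which the systolic
  flow/pressure wave travels down the aorta. 4D flow MRI (time-resolved,
  three-directionally velocity-encoded phase-contrast imaging) records
  blood velocity throughout the thoracic aorta; the wave's arrival time
  at cross-sectional planes placed every 5 mm along the vessel centerline
  rises linearly with centerline distance, and

  `PWV = 1 / slope` of the ordinary-least-squares fit of arrival time
  τ (s) on distance s (mm), reported in m/s.

  Three arrival detectors are implemented: **time-to-foot** (diastolic
  baseline ∩ extrapolated 20–80% upstroke line), the **50%-rule** (first
  upstroke crossing of half peak flow), and **cross-correlation** (lag
  against the most proximal plane, refined to sub-sample precision).

* **Distensibility coefficient (DC)** — the relative diameter change of a
  single aortic cross-section per unit pulse pressure,

  `DC = (2·Δd/Dd) / ΔP` in 10⁻³/kPa,

  where Δd is the systolic diameter excursion, Dd the end-diastolic
  diameter (both from a 2D CINE series tracked with a phase-based,
  Morphon-style registration) and ΔP the brachial pulse pressure
  converted from mmHg (1 mmHg = 0.133322 kPa).

At the cohort level the package fits the linear reference model
`PWV = β₀ + β_age·age + β_male·male + ε`, computes age/sex-adjusted
residual correlations, Bland–Altman limits of agreement, and paired
Wilcoxon comparisons between the three PWV algorithms.

Because clinical 4D flow data are rarely shareable, the package ships
first-class phantom generators: a candy-cane flow phantom (straight
ascending limb, semicircular arch, straight descending limb) whose pulse
propagates at a prescribed PWV, a pulsating-disk CINE phantom with an
exactly known diameter curve, and a cohort simulator with configurable
regression coefficients.

## Worked example

```python
import numpy as np
from aortapwv import PhantomSpec, make_flow_phantom
from aortapwv.pipeline import pwv_pipeline

spec = PhantomSpec(true_pwv=5.0, noise_sd=0.05, seed=3)   # 5 m/s ground truth
field, centerline, mask = make_flow_phantom(spec)
sp = np.asarray(field.spacing)
start = tuple(np.round(centerline.points[0] / sp).astype(int))
end = tuple(np.round(centerline.points[-1] / sp).astype(int))
print(pwv_pipeline(field, start, end).summary())
```

```
Pulse wave velocity — linear transit-time fit
method     PWV (m/s)     R^2  planes  valid
ttf            4.983   0.999      61   True
half_peak      4.960   1.000      61   True
xcor           4.947   1.000      61   True
```

All three detectors recover the generating 5 m/s within 1% despite 5%
velocity noise; 61 planes cover the ~300 mm thoracic centerline at 5 mm
spacing. Distensibility works the same way:

```python
from aortapwv import (CinePhantomSpec, make_cine_phantom, Contour,
                      BloodPressure, DistensibilityModel)

cine, truth = make_cine_phantom(
    CinePhantomSpec(dd_mm=30.0, delta_d_mm=2.0, noise_sd=0.01, seed=5))
f0 = cine.frames[0]
c0 = Contour.from_mask(0, f0 > 0.5 * (f0.min() + f0.max()))
print(DistensibilityModel(cine, c0, BloodPressure(120, 80)).fit().summary())
```

```
Distensibility — ascending aorta
  end-diastolic diameter Dd :   29.80 mm
  systolic excursion dd     :    2.03 mm
  pulse pressure            :    40.0 mmHg (5.333 kPa)
  DC                        :   25.60 x 1e-3/kPa
```

The analytic value for a 30 mm vessel expanding 2 mm at 40 mmHg is
25.0 × 10⁻³/kPa; the tracked estimate is within 3%.

A console script `aortapwv` exposes the same pipelines
(`make-phantom`, `estimate-pwv`, `estimate-dc`, `cohort-stats`).

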
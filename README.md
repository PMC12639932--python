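# jointaxis

Identification of **fixed and moving joint centers of rotation** from the
motion of two rigid body segments, using the analytical instantaneous
center/axis of rotation (ICOR/IAOR) of their relative motion.

Musculoskeletal models place every joint center and axis at a generic,
scaled location. Errors of a centimeter in a hip or knee center propagate
into double-digit percentage errors in computed joint torques, so
personalizing joint placement from motion data matters for anyone running
inverse-kinematics or inverse-dynamics pipelines (OpenSim-style workflows,
IMU-based movement analysis, rehabilitation and ergonomics studies). Most
functional-calibration methods assume a center that is *fixed* in one
segment; the tibiofemoral joint violates that assumption — its center
migrates with the flexion angle. The ICOR method has no such restriction
and works with both segments in motion.

## The method

At any instant the motion of a child segment relative to a parent segment
is a pure rotation about a point (planar) or a line (3D). With the relative
angular velocity **ω**ᵣₑₗ, the relative velocity **v**ᵣₑₗ of the child
origin observed in the parent frame, and the child origin position
**r**ᵣₑₗ, the instantaneous center expressed in the parent frame is

```
c = (ω_rel × v_rel) / ‖ω_rel‖² + r_rel,        e = ω_rel / ‖ω_rel‖
```

and the instantaneous axis is the line `c + t·e`. For a revolute or ball
joint every sample of `c` (or every line `(c, e)`) passes through the joint
center; for an angle-dependent joint the samples trace the moving center
`c(φ)`. Estimators built on this:

* **fixed planar center** — 1.5-IQR outlier removal, zero-phase low-pass
  filtering of the ICOR coordinates over time, per-coordinate statistics;
* **fixed 3D center** — the point minimizing the summed squared
  perpendicular distance to all instantaneous axes (normal equations
  `Σ(I − eeᵀ)x = Σ(I − eeᵀ)c`);
* **moving center** — cubic smoothing splines of the ICOR coordinates over
  the joint angle (csaps convention, `p·Σ(y−s)² + (1−p)·∫s″²`), a ±1 cm
  margin outlier rejection around the fit, low-pass filtering, refit; the
  child's translation path is then reconstructed by marching
  `bₙ = R(Δφ)(bₙ₋₁ − cₙ) + cₙ` with `cₙ` the midpoint of consecutive
  smoothed centers.

Because velocities enter a denominator, noisy samples taken near motion
reversals are heavy-tailed outliers; the denoising stack above is part of
the method, not an afterthought.

Synthetic mechanism generators with *exact analytic velocities* (double
pendulum under gravity, ball joint, planar knee-like joint with translation
splines of the flexion angle) provide ground truth for verification, plus
seeded white-Gaussian velocity noise to emulate sensor error.

## Worked example: recover a hip-like joint center

```python
import numpy as np
import jointaxis as ja
from jointaxis.synthetic_models import (
    BallJointConfig, NoiseSpec, add_noise, default_squat_parent_excursion,
)

# 1) simulate a ball joint through a calibration movement, both segments moving
cfg = BallJointConfig(parent_excursion=default_squat_parent_excursion())
pelvis, femur, truth = ja.ball_joint(cfg)

# 2) corrupt the velocity channels (noise std 0.02 m/s and rad/s)
pelvis_n = add_noise(pelvis, NoiseSpec(var_linear=4e-4, var_angular=4e-4, seed=11))
femur_n  = add_noise(femur,  NoiseSpec(var_linear=4e-4, var_angular=4e-4, seed=12))

# 3) relative motion -> per-step instantaneous axes -> least-squares center
axes = ja.icor_relative(ja.relative_motion(pelvis_n, femur_n))
est = ja.fixed_center_lsq(axes)
print(f"estimated center [m]: {np.round(est.point, 4)}")
print(f"true center      [m]: {truth.center_parent}")
err = np.linalg.norm(est.point - truth.center_parent) * 1e3
print(f"recovery error: {err:.2f} mm from {est.n_lines} axes")
```

prints

```
estimated center [m]: [-0.0492  0.2481 -0.0152]
true center      [m]: [-0.05  0.25 -0.02]
recovery error: 5.23 mm from 1000 axes
```

— the center is recovered to millimeters although no single axis is
reliable and both segments moved throughout. The knee workflow is one call:

```python
from jointaxis.workflows import knee_study
correlations, reconstruction = knee_study(seed=1)
print((reconstruction.set_index("condition") * 1000).round(3))
```

```
           rmse_x  rmse_y
condition
MA-WO       0.695   0.752
BW-WO       0.726   0.818
```

i.e. the tibia's translation path in the femur frame, rebuilt purely from
noisy ICOR estimates, is sub-millimeter accurate for this realization
(MA-WO / BW-WO: moving-average or Butterworth filtering after outlier
removal).

## Command line

Every step is also a CLI subcommand operating on STO/CSV motion files:

```
jointaxis simulate-knee --out knee.sto
jointaxis add-noise --var-linear 4e-4 --var-angular 4e-4 --seed 7 \
    --inp knee.sto --out knee_noisy.sto
jointaxis estimate-knee --inp knee_noisy.sto --out curve.csv
jointaxis reproduce-tables --seed 1 --out-dir reports
```

`reproduce-tables` writes the pendulum condition table, knee correlations
and reconstruction RMSEs, and the hip-center report as CSVs; identical
seeds give byte-identical reports.

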
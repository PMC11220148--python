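# mattforce

Vector (normal + shear) contact forces at the human–mattress interface,
computed by registering a grid pressure-mat recording to a 3D scan of the
deformed mattress surface.

## The problem

A pressure mat under a lying person reports only scalar forces — the
magnitude of the load on each sensor cell, with no direction. On a deformed
mattress the support force at each point acts along the local surface
normal, so the measured field also contains horizontal (shear) components:
"lateral" across the mat width and "axial" along its length. Those shear
components matter for tissue loading and, together with the resultant
per-region forces and moments, are the boundary conditions a
musculoskeletal model of a sleeping posture needs.

`mattforce` reconstructs the full vector force field from two routine
measurements:

1. a 24×48 pressure-mat recording (36.25 mm cell pitch), time-averaged over
   the central window of the trial and converted to Newtons;
2. a point-cloud scan (PLY) of the indentation left in a vacuum positioning
   mattress.

The method:

- expand the pressure grid into a 3D point cloud, placing each nonzero cell
  at its center with depth `F' = −(F / F_max)·(Z_max − Z_min)` so the
  pressure image mimics the indented surface;
- align it to the scan with a deterministic coarse initialization
  (centroid + in-plane principal axes), point-to-point ICP, and a final
  image-correlation refinement of the in-plane pose;
- bin the registered scan points into sensor cells and average their unit
  normals per cell: `n̂ₛ = (Σnᵢ/N) / |Σnᵢ/N|`;
- scale each cell's scalar force along its normal, `F⃗ₛ = F·n̂ₛ`, giving per-cell
  force vectors `(f_x, f_y, f_z)`;
- validate by force balance — `F_Z = Σ f_zᵢ` should match body weight `G`
  while `F_X, F_Y` should be near zero — and reduce each body region to a
  wrench: resultant `F⃗_A = ΣF⃗ₛᵢ`, couple `M⃗_A = Σ r⃗ᵢ×F⃗ₛᵢ`, and an
  application point `r⃗_A` in the sensor plane (the generalized center of
  pressure), with any moment component parallel to `F⃗_A` reported
  separately as the free (residual) moment.

An sEMG module (20–500 Hz Butterworth band-pass, 50 Hz notch, 66.7 ms
moving-RMS envelope, %MVC normalization, Spearman correlation) supports the
muscle-activity side of validating the model that consumes these boundary
conditions.

A synthetic-scenario generator (`mattforce.synth`) produces
Gaussian-lobe indentation surfaces with closed-form normals, pressure grids
whose vertical components sum exactly to a prescribed body weight, a known
rigid mat-to-scanner transform, and optional measurement noise — so every
pipeline stage can be tested against exact ground truth.

## Worked example

Generate a synthetic supine trial (63 kg body, ~24k-point scan), run the
pipeline, and validate the balance:

```
$ mattforce synth --seed 3 --preset supine --out-dir demo
wrote surface.ply (23653 pts), pressure.csv, true_transform.json to demo

$ mattforce compute --pressure demo/pressure.csv --ply demo/surface.ply \
      --weight-n 617.4 --units n --out demo/field.csv
F_z = 617.53 N (100.02% of body weight); F_x = 0.54 N, F_y = 0.16 N; total pressure = 625.02 N (101.23% of body weight)
```

The vertical components sum to 100.02% of the 617.4 N body weight — static
equilibrium recovered to 0.02% — while the horizontal sums stay below 1 N,
as they must for a body at rest. The total *scalar* pressure (625.0 N)
exceeds the vertical sum because tilted cells push harder than their
vertical share; on strongly indented real mattresses that excess reaches
~30% of body weight, which is why raw pressure-mat totals overestimate
load.

Reduce the field to per-region boundary conditions:

```
$ mattforce regions --field demo/field.csv --posture supine --out demo/bc.json
legs:  F_A = (0.09, 7.98, 119.46) N,  r_A = (430.9, 442.7) mm,  residual = -0.0329 N*m
hips:  F_A = (0.26, 0.09, 201.01) N,  r_A = (427.7, 773.9) mm,  residual = 0.0236 N*m
waist: F_A = (0.12, -0.82, 88.52) N,  r_A = (433.0, 1013.7) mm, residual = 0.0360 N*m
chest: F_A = (0.08, -6.53, 180.87) N, r_A = (436.5, 1273.0) mm, residual = -0.0034 N*m
head:  F_A = (-0.02, -0.55, 27.67) N, r_A = (432.3, 1543.7) mm, residual = -0.0074 N*m
```

Each region's distributed load is replaced by one force at one point plus a
small free moment; the hips carry the largest share (201 N of 617 N), and
every application point sits near the mat's mid-axis (x ≈ 435 mm), as
expected for a supine posture. `demo/bc.json` holds the same wrenches in SI
units (N, N·m, m) for direct use as model boundary conditions.

The same chain works on real data: point `--pressure` at a mat recording
(multi-frame CSV or JSON; `--units mmhg` converts via
133.322 Pa/mmHg × cell area), `--ply` at the scanner export, and supply the
subject's weight.

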
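# Methods

This note documents the model, the numerical choices, and the limits of
what the test suite demonstrates.

## Physical model

A body at rest on a mattress is in static equilibrium: the distributed
support force integrated over the contact patch must equal body weight
vertically and vanish horizontally. A grid pressure mat samples the
magnitude of that distributed force at 24×48 sensor cells (36.25 mm pitch)
but not its direction. The central modelling assumption is that the support
force at each cell acts along the local outward normal of the deformed
mattress surface, so the cell's force vector is

    F⃗ₛ = F · n̂ₛ,

where F is the cell's scalar force in Newtons and n̂ₛ the unit mean normal
of the scanned surface points lying inside the cell footprint. This is a
frictionless-contact idealization: any tangential (frictional) component of
the true interface traction is not represented, and the horizontal
components recovered here are purely geometric — the projection of the
normal force onto the mat plane where the surface is tilted.

Two consequences are worth keeping in mind when reading outputs:

- Σ‖F⃗ₛ‖ ≥ Σ f_z always, with equality only for a perfectly flat contact.
  The total scalar pressure therefore *over*-states the supported weight on
  an indented surface (by ~30% in strongly deformed conditions), while the
  vertical component sum is the physically meaningful comparison to G.
- f_z ≥ 0 everywhere by the orientation convention (normals point out of
  the mattress, toward the body), so the field is a support field, never a
  pull.

## Pipeline stages and numerical choices

**Windowing and averaging.** Multi-frame recordings are reduced to one grid
by averaging the frames in the central window (default 10 s of a 30 s
trial; closed interval centered on the timestamp midpoint). This discards
settling-in/rising-out transients. The reduction is a plain per-cell
arithmetic mean.

**mmHg → N.** Sensor pressures are converted as
F = P · 133.322 Pa/mmHg · (0.03625 m)², i.e. the cell's pressure applied
uniformly over its full pitch area. The constant is exposed so calibrated
devices can override it. This is the simplest defensible conversion; any
sensor-specific active-area calibration is out of scope.

**Pressure-cloud expansion.** Each nonzero cell becomes one 3D point at its
center with z = −(F/F_max)·(Z_max − Z_min), the z-range taken from the
target scan. Zero cells are omitted: they carry no force, and a rim of
z = 0 points would drag the registration toward the undeformed plane.

**Registration.** Three deterministic stages replace the manual
visual alignment a human operator would perform:

1. *Coarse*: centroid match plus in-plane principal-axis rotation, with the
   four axis-sign candidates scored by nearest-neighbor RMSE.
2. *ICP*: point-to-point, nearest-neighbor correspondences within
   72.5 mm (two cell pitches), SVD/Kabsch update, stop at 200 iterations or
   1e−6 relative RMSE change. Point-to-point is preferred over
   point-to-plane because the source cloud's z is a normalized-pressure
   surrogate, not a true depth, so plane residuals have no better footing.
3. *Image-correlation refinement*: pressure is monotone in indentation but
   not proportional to it, so the surrogate z profile disagrees with the
   scanned depths lobe by lobe; ICP resolves that disagreement partly by
   shifting in-plane (observed bias: up to ~18 mm, i.e. half a cell, for
   laterally concentrated load patterns). The final stage corrects it by
   maximizing the Pearson correlation between the scalar pressure image and
   the indentation depth sampled under each (shifted, rotated) cell center
   — for indentation lobes that are individually symmetric, this objective
   peaks at the true in-plane pose regardless of per-lobe amplitude
   mismatch. Optimized with Nelder–Mead (initial steps 15 mm / 0.03 rad);
   the stage is on by default and switchable off.

An operator-supplied initial transform short-circuits the coarse stage.

**Normals.** Scans that ship without normals get them from a local plane
fit: the smallest-eigenvector direction of the k = 12 neighborhood
covariance, flipped to z ≥ 0. Per cell, point normals are averaged
componentwise and renormalized; a mean with norm < 1e−9 (cancelling
normals) raises rather than silently verticalizing, since it indicates a
registration failure. Cells with pressure but no scan points (scan
shadows) default to borrowing the mean normal of the 8 nearest scan points
within two cell pitches (fallback vertical); "vertical" and "strict"
policies are selectable.

**Cell binning** is half-open on both axes with the lower-left corner
inclusive, so every point lands in exactly one cell; out-of-footprint
points are discarded and counted.

**Wrench reduction.** Region resultants are F⃗_A = ΣF⃗ᵢ and
M⃗_A = Σ r⃗ᵢ×F⃗ᵢ about the mat's lower-left origin (N·mm internally; exports
convert to N·m and m and state the origin). The textbook "invert the
cross-product matrix" step for the application point is ill-posed — a
cross-product matrix has rank 2 for every F — so the implemented resolution
restricts r⃗_A to the sensor plane z = 0, solves r⃗×F⃗_A = M⃗_⊥ by least
squares (minimum-norm within the plane when the force is horizontal and
the system degenerates), and reports the parallel component of M⃗_A as an
explicit free moment. For the dominant case f_z ≠ 0 the solve is exact and
r⃗_A generalizes the center of pressure.

**sEMG.** Fourth-order Butterworth 20–500 Hz band-pass and a Q = 30
second-order 50 Hz notch, both applied forward–backward (zero phase) so
envelope timing stays aligned; 66.7 ms centered moving-RMS (100 samples at
1500 Hz, truncated at edges); %MVC normalized by the maximum envelope peak
across MVC repetitions. The trial statistic defaults to the envelope mean
(sustained activity over the trial) and can be switched to peak.
Correlation between measured and predicted activity uses Spearman rank
correlation with mid-ranked ties.

## Synthetic scenarios and what the tests show

The generator builds surfaces as sums of Gaussian indentation lobes,
z(x, y) = −Σ A_k·exp(−Δx²/2σx² − Δy²/2σy²), chosen because depth, gradient
and unit normal are closed-form. Per-cell vertical loads are proportional
to load-share-weighted local depth, rescaled so Σf_z equals the prescribed
body weight exactly, then converted to scalar cell forces F = f_z/n_z using
the analytic normal at the cell center. A seeded in-plane transform
(±6°, ±50 mm, ±10 mm vertical) separates mat and scanner frames. The
"stated" noise condition applies 0.5 mm Gaussian point noise after the
transform and pressure noise of 1% of the peak cell force. Presets:
a five-lobe supine pattern (head/chest/waist/hips/legs, load shares
0.08/0.31/0.11/0.35/0.15, symmetric about the mid-axis) and a
laterally offset four-lobe side-lying pattern (head/shoulder/hips/legs,
0.10/0.30/0.40/0.20); depths 25–65 mm and widths 70–180 mm are in the range
of soft-mattress indentation under an adult of ~450–750 N. Default body
weight 617.4 N (~63 kg, mid-cohort). Seeds jitter lobe centers ±15 mm and
depths ±10%, so different seeds exercise different geometry
deterministically.

On these scenarios the pipeline recovers the vertical balance to within
0.15% noise-free (band asserted: ±0.5%), per-cell force vectors to within
~0.8–1.8% RMS (asserted < 2%), a known transform between identical clouds
to < 0.1° / 0.1 mm, and the noisy-condition balance well inside 95–105%.
Default problem size is a ~24k-point scan (8 mm lattice over the
0.87 × 1.74 m sensor footprint), which one trial processes in about a
second.

What this does **not** show about real data: the lobes are smooth and
individually symmetric, which is exactly the regime where the correlation
refinement is unbiased; real indentations have asymmetric lobes, scan
holes, rims and clothing artifacts, so registration accuracy on real scans
should be checked against the visual overlay rather than assumed. The
generator also enforces the frictionless model by construction — it cannot
detect violations of the normal-direction assumption itself, only errors
in recovering it.

## Region layouts

Default head/chest/waist/hips/legs bands span the full mat width and
partition the length (cells 40–47, 31–39, 25–30, 18–24, 0–17). They are
editable starting points meant to be adjusted per subject against the
pressure heatmap — not anatomical truth — and region configs are ordinary
YAML/JSON files. Regions must not overlap; wrench exports record the
moment origin so downstream models cannot misinterpret r⃗_A.

## Known limitations

- Shear here is geometric (tilted normals), not frictional; surfaces with
  significant tangential traction will be underestimated.
- The scalar force per cell is applied unchanged even where deformation
  changes the effective cell area.
- The mmHg conversion assumes the full cell pitch as active area.
- The correlation refinement assumes the loaded region's depth/pressure
  images are correlated and lobes roughly symmetric; a pathological load
  pattern could in principle mislead it, in which case an operator-supplied
  initial transform and `refine_correlation=False` restore full manual
  control.
- The 24×48 grid dimensions and pitch are fixed; mats with other layouts
  would need the grid constants generalized.
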
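# Methods

This note documents the models, estimators and numerical choices behind
`carmtomo`, and what the simulation-based tests do and do not establish.

## Coordinate model

The world frame sits at the centre of the calibration phantom (the nominal
isocenter), `z` along the phantom axis. For gantry angle β the source lies
at `SOD·(cos β, sin β, 0)`; the ideal detector centre is on the
source→origin ray at distance `SDD` from the source. Detector misalignments
are extrinsic rotations of the panel basis in the order roll φ (about the
panel's vertical axis), pitch θ (about its horizontal axis), skew η (about
its normal), plus in-plane pixel offsets `(H, V)` that translate the panel.
With this construction the piercing point (image of the world origin) is
always at pixel `(O_h − H, O_v − V)`, i.e. offsets and piercing-point
position are exact negatives — a convenient invariant used throughout.

Defaults mirror a small flat-panel C-arm: 444×540 pixels of 0.8 mm,
SDD 1250 mm, SOD 625 mm (magnification 2), arcs of 120° with 15–49 views.

## Per-view geometric calibration

The phantom: two rings of eight 0.8 mm ball bearings on circles of diameter
49.1 mm separated 35 mm, in a PMMA cylinder wall (45.5/49.5 mm). Each ring
projects to an exact conic; the pair encodes the full per-view geometry.

Six staged steps provide closed-form estimates:

1. **Centroids** — Otsu threshold, morphological cleaning, and
   threshold-subtracted centres of mass, sub-0.05 px on resolved beads.
   Blobs whose integrated intensity marks them as two overlapping beads
   are either split by a two-Gaussian mixture fit (exact for the Gaussian
   blob model, reliable above ~1 px separation) or kept as "weight-2"
   markers whose centroid is the mean of the two projections.
2. **Ring classification** — largest vertical gap with at least five
   markers per side; collinear or ambiguous layouts raise errors that
   point at the override mechanism.
3. **Piercing point / offsets** — midpoint of the two conic centres
   (exact at zero inclination).
4. **Skew** — slant of the line joining the conic centres relative to the
   detector's vertical axis.
5. **Inclinations** — pitch from the converging point `P_θ` of the two
   outer common tangents (the cylinder silhouette): with `v_θ` the distance
   from the piercing point to `P_θ` along the projected phantom axis and
   `Z_S = 2·R·L1·L2 / (H·(L2 − L1))` from the inner gap `L1` and outer span
   `L2` of the ellipses along that axis, the exact projective relations are
   `sin θ = SDD/v_θ` and `Z_S ≈ SDD/cos θ`, hence
   `θ = arctan(Z_S·cos φ / v_θ)` (the residual `O((H·tan θ/Z)²)` term is
   0.06° at θ = 60°). The zero-pitch branch triggers when the two ellipses
   have equal extents along the axis (the "lengthier ellipse" criterion) to
   relative 10⁻³, or when the silhouette tangents are parallel.
   Roll is the argmin of a convergence cost `C_φ`: for a candidate φ the
   two ring conics are predicted by exact projection and compared with the
   measured pair (centres, semi-axes, and the roll-sensitive long-axis
   orientations); magnification nuisances (piercing column, SOD, SDD) are
   profiled out by an inner least squares, and Nelder-Mead runs over φ with
   multi-start {−45°, 0°, +45°} (tolerance 10⁻⁴ on φ). Pitch and roll
   alternate (≤3 rounds, 0.01° tolerance) because each equation involves
   the other angle.
6. **Source/detector** — `SDD = Z_S·cos θ`; `SOD = R·√(1+(SDD/a_mm)²)`
   from the mean projected semi-major axis `a_mm`.

Two refinement stages then absorb the staged approximations:

* a bounded least-squares **conic polish** over (η, θ, φ, piercing, SOD,
  SDD) matching the measured conics against analytically projected ring
  conics, with structured restarts at pitch/roll sign flips (the staged
  estimates can land in the mirrored basin under combined inclinations);
* a **bead-reprojection fit** over the same parameters plus the apparent
  phantom azimuth, matching each measured centroid to its nearest
  predicted bead (weight-2 centroids to the mean of their two nearest
  predictions). This restores the full statistical strength of the
  individual markers and makes the calibration robust to sub-0.1 px
  centroid noise. When the first geometry estimate exists, all markers are
  re-measured by model-driven K-Gaussian mixture fits at the predicted
  positions, which resolves arbitrarily crowded views.

Scan-level logic retries views whose marker pattern defeats the ellipse
stage (too many coincident beads) from the nearest calibrated neighbour,
optionally pinning SOD/SDD at the scan medians — they are mechanical
constants of a scan, while the per-view detector-plane parameters are not.
A view is declared failed above 1 px reprojection RMS; a scan fails when
more than 20% of views do.

Measured accuracy on noise-free simulated scans (per-view skew/pitch/roll
uniform in ±15°, offsets in ±20 px, 25 views over 120°): worst-case errors
≈ 0.01° (skew), 0.3° (pitch/roll), 0.02 px (offsets) across multiple seeds
— comfortably inside the (0.2°, 1°, 1°, 0.5 px) contract the module is
tested against.

## Adaptive refinement

The per-acquisition refinement corrects only `H`, `V` and skew `S` (errors
in SDD, pitch and roll are deliberately neglected). Workflow: preliminary
FDK from the stale calibration → 3-D rigid mutual-information registration
of the surface mask (Mattes MI, 100-bin joint histogram, dense sampling,
3-level multi-resolution Powell plus a fine full-resolution polish; both
volumes pre-smoothed by one voxel so the metric has sub-voxel gradients) →
forward projection of the registered mask → per-view 2-D rigid
registration → closed-form update

    H_corr = H + ΔH_reg + O_h − (O_h·cos ΔS_reg − O_v·sin ΔS_reg)
    V_corr = V + ΔV_reg + O_v − (O_h·sin ΔS_reg + O_v·cos ΔS_reg)
    S_corr = S − ΔS_reg

with `(O_h, O_v)` the detector centre; `H`/`V` here are the piercing-point
offsets from the centre. The `ViewCorrection` fields carry the 2-D
transform in the rotation-about-pixel-origin convention this update
expects; `ViewCorrection.from_center_transform` converts from the
centre-rotation parameters the registrar estimates.

The 2-D similarity is normalized cross-correlation between the warped mask
*thickness* projection and the measured projection, evaluated on a ±4 px
band around the body contour (the interior is excluded because bone
structure is not proportional to thickness and biases the pose; a signed-
distance-field variant is used when only a binary silhouette is given).
Translation is initialized by phase correlation; Nelder-Mead refines
(ΔH, ΔV, ΔS). On the digit-bearing limb sample this reaches ≈0.1 px /
0.05° per view, and recovers injected per-view perturbations (±10 px,
±3°) within 0.5 px / 0.2°.

A global mask-pose error is partially degenerate with coherent per-view
corrections: when the preliminary FDK is heavily distorted the MI
registration can trade a small pose offset against view-wise corrections
without hurting the data fit. An optional second pass (re-reconstruct,
re-register, re-refine) mitigates this; marker-based registration is the
documented extension point for extreme cases.

## Forward model and reconstruction

The system matrix is a ray-driven Joseph projector (plane stepping along
the dominant ray axis, bilinear transverse interpolation) with a matched
scatter-form adjoint — the pair is adjoint to rounding error (dot-product
tests at 10⁻¹⁶ in double precision), which the Krylov solver requires.
Accumulation is single precision; float64 inputs are honoured for tests.

**FDK** generalizes filtered backprojection to per-view geometry: cosine
weighting about each view's piercing point, row-wise ramp filtering
(spatial-domain Ram-Lak kernel, zero-padded FFT convolution, blended with
a Hann window at 20% weight), then voxel-driven backprojection with the
`SDD·SOD/U²` distance weight appropriate for detector-plane filtering and
angular weights proportional to the local view spacing. A dense full-orbit
cylinder reconstructs to its true attenuation within 0.1%.

**SCoLD** solves TV-minimization with data and support constraints by
Split Bregman. Per outer iteration: the quadratic u-subproblem
`(μAᵀA + λ∇ᵀ∇ + γI)u = μAᵀf^k + λ∇ᵀ(d−b) + γ(v−b_v)` by warm-started
conjugate gradients (12 iterations or relative residual 10⁻⁴); isotropic
2-D shrinkage `d = max(|g|−1/λ, 0)·g/|g|` of the in-slice gradients;
Bregman updates of the TV variables; the support projection
`v = clamp(u+b_v, 0, ∞)` inside Ω and 0 outside (the Euclidean projection
implied by the constraints), with its Bregman update; and the data Bregman
update `f^{k+1} = f^k + f − Au`. Defaults μ=35, λ=5, γ=0.02, 35 outer
iterations. Initialization is all-zero. Both the raw iterate `u` and a
masked, non-negative variant are returned; the masked volume is the
default output. Gradients are 2-D in-slice, so z-invariant objects stay
z-invariant and strongly z-varying objects can show mild horizontal
banding in coronal views — the known cost of the 2-D splitting.

## Metrics

SAI is the total variation (in-slice forward-difference gradient
magnitudes) of the difference to the reference volume; LiVA is the RMSE
inside a region of interest bounded by the sample's external contour
(threshold, largest component, closing with edge padding, hole fill).
SAI is reported raw by default (it scales with volume size; a per-voxel
normalization is available and the mode is recorded in every report).

## Synthetic data

The study generator emulates a small-extremity acquisition: an
"ellipsoid-limb" sample (soft-tissue ellipsoid at 0.02/mm with two
bone-like inserts at 0.05/mm and three finger-like digits with bone cores;
digits make the silhouette rotation-informative the way real extremities
are), its exact support mask, a 25-view/120° scan, a calibration-phantom
scan at the same angular positions, and per-view detector perturbations
(±8 px offsets, ±2° skew by default) modelling the non-repeatability of a
hand-moved C-arm. Noise is optional Poisson on transmitted counts
(I₀ = 10⁵ by default); the acceptance and accuracy tests run noise-free,
so they establish correctness of the estimators and solvers, not their
photon-statistics robustness. Other idealizations: monochromatic rays, no
scatter, no detector blur or lag, bead blobs rendered as Gaussians with σ
equal to the projected bead radius, and exactly equiangular beads — the
latter makes some view angles project bead pairs on top of each other,
which the merged-marker machinery above is designed to survive.

The bead mounting azimuth defaults to 11.25° (half the bead spacing),
which maximizes the worst-case projected bead separation on 5°-spaced
views.

## Problem sizes and tolerances

The test suite runs at desk scale on one CPU core: the calibration sweep
at the full 444×540 detector, refinement recovery at 64³ voxels, the
limited-data SCoLD benchmark at 96³ voxels / 120×120 detector bins with
the full 35 iterations, the well-posed full-orbit check at 48³, and the
plain-TV equivalence on a 20×20×6 slab against an independently written
Split Bregman reference. The pipeline rebins the 0.8 mm panel by 2 for
reconstruction. Key numerical tolerances: ellipse fits are exact for conic
points (preconditioned linear least squares); Nelder-Mead roll tolerance
10⁻⁴ degrees; CG relative residual 10⁻⁴; pitch degeneracy threshold 10⁻³
relative; view failure above 1 px reprojection RMS.

## Known limitations

* Calibration assumes the source lies in the phantom's equatorial plane;
  axial source offsets are absorbed into the piercing point.
* The refinement corrects detector-plane parameters only; SDD/pitch/roll
  drifts between calibration and acquisition are not recovered.
* The mask-pose/per-view-correction degeneracy discussed above.
* 2-D TV regularization (3-D TV is the natural extension).
* The simulator does not model scatter, beam hardening or focal-spot blur,
  so the accuracy figures quoted here are upper bounds on real-system
  performance.
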
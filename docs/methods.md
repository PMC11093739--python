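# Methods

This note documents the models, conventions and numerical choices behind
`duoview`, and what the synthetic phantoms do and do not emulate.

## Conventions

All volumetric data is indexed `(z, y, x)` with `z` the detection axis and
plane 0 the first TIFF page.  Physical units are µm for space and hours for
time throughout.  Every derived quantity (FWHM, waist, NA, MSD) is reported
in these units.

## Focus metric (DCTS)

Each z-plane is scored by the Shannon entropy of its normalized 2D type-II
DCT.  The plane is mean-subtracted (so a constant offset carries no
information), transformed with an orthonormal DCT, optionally restricted to
the quarter-disk of radius `support_fraction·√(H²+W²)` in coefficient index
space, and the retained coefficients are normalized to a distribution
`p_k = c_k²/Σc_j²`; the score is `H = −Σ p_k ln p_k` (natural log).

Choices and their rationale:

- **Power normalization** makes `p` a genuine probability distribution with
  the clean bounds `0 ≤ H ≤ ln K` (`K` = retained coefficients).  The
  magnitude variant (`dcts_norm: l2`, `p_k = |c_k|/Σ|c_j|`) is provided for
  compatibility with the autofocus literature; both orderings agree on the
  test ensembles.
- The score is invariant to positive rescaling of the image, so
  depth-dependent attenuation does not move the view crossover — only blur
  does.
- An all-zero (after mean subtraction) plane scores 0 by definition.
- Smoothing: quality profiles are smoothed with a centered moving average
  (default window 5 planes, shrink-to-fit at the edges) to stabilize the
  crossover without displacing it.
- A corner impulse does **not** score exactly `ln K`: DCT coefficients of an
  impulse follow a cosine envelope, not a flat spectrum (that identity holds
  for DFT magnitudes).  The bound `H ≤ ln K` is what the implementation
  guarantees.

## Switching plane and sigmoidal fusion

The switching plane is the smallest z where the sign of
`score_view1 − score_view2` flips relative to its sign at plane 0 (ties
break toward the smaller index).  Without a crossover the fusion degenerates
to the everywhere-better view (plane 0 or the last plane).  Views are
blended with `w₂(z) = 1/(1 + exp(−(z − z_switch)/s))`, `w₁ = 1 − w₂`; the
slope `s` is measured in planes (default 3, blending over ~±10 planes).
After blending, a constant camera background is subtracted and negative
values are clipped to zero (intensities are counts).  `z_switch` is
recomputed per time point; the registration can be reused (`register: once`)
or refreshed (`per_timepoint`).

When the aligned view was resampled, its out-of-bounds rim is a constant
fill; the sharp rim boundary would add spurious high-frequency power
precisely to the blurred planes.  The pipeline therefore scores a central
crop (default: 10% of each in-plane border excluded,
`quality_crop_fraction`).

## Rigid registration

`register_rigid` wraps a 6-DOF Euler registration (Mattes mutual
information, 32 bins, exhaustive sampling, 3-level shrink-4/2/1 pyramid,
regular-step gradient descent) — mutual information because the two views
have different depth-dependent intensity profiles, exhaustive sampling
because it makes the result deterministic.  The returned
`RigidTransform` maps fixed-frame physical points to moving-frame points
(`q = R(p − c) + c + t`, `R = Rz·Ry·Rx`); resampling is an in-package
trilinear `scipy.ndimage` pull-back so the transform convention is
independent of the registration backend.  On bead phantoms the recovery
error is ~0.02 voxel / 0.04° for translations up to 3 voxels and rotations
up to 2°.  Constant images raise a convergence error (mutual information is
undefined without structure).

## Optical characterization

Line profiles are fitted with `f(x) = a + b·exp(−(x−μ)²/(2σ²))` by
Levenberg–Marquardt, initialized from moments (`a ← min`, `b ← max−min`,
`μ ← argmax`, `σ` from the second moment of the offset-subtracted profile)
with `σ` constrained positive.  Derived quantities:

- `FWHM = 2σ√(2 ln 2)` — the standard Gaussian relation.
- `w₀ = 2σ` of the *intensity* profile — the 1/e² radius convention
  (`I ∝ exp(−2x²/w₀²)`).
- `NA_eff = nλ/(πw₀)`; `z_r = πw₀²n/λ`.  The Rayleigh length is also
  available empirically via `fit_beam_profile`, which fits measured per-z
  widths to the caustic `w(z) = w₀√(1+((z−z₀)/z_r)²)`; both routes agree to
  2% on simulated beams.

Bead-PSF measurement detects local maxima above a user threshold (3-voxel
exclusion radius; border-clipped beads discarded), fits axis-aligned line
profiles along x and z through each bead, and averages the per-bead FWHMs.
Because a 3D Gaussian is separable, an axis-aligned profile through any
voxel of the bead has the true σ regardless of subvoxel centering, which is
why the noiseless recovery is exact to sampling error (<2%) even for a
lateral σ below one voxel.

## Track statistics

`msd₃D(t) = (1/N) Σᵢ (rᵢ(t) − rᵢ(0))²` — the ensemble, origin-anchored
definition with no sliding-window time averaging.  Lags are measured from
each track's own first frame; tracks contribute only at lags they cover and
the per-lag `N` is reported, so dropout is visible rather than silently
reweighted.  Speeds are per-step Euclidean displacement over elapsed time
(frame gaps divide by the actual gap); a per-track mean speed table is also
emitted, since "cell velocity" may mean either.  Path length is the sum of
consecutive displacements (single-point tracks: 0).

The CSV reader accepts the loose header conventions of manual-tracking
exports (any column containing "track" is the id; "frame"/"t"/"spot frame"
the frame; columns containing "intensity"/"mean" ride along untouched, in
whatever counts the export used).

## Shape analysis

2D masks are stitched top-down in z: each mask links to the previous plane's
mask of maximal IoU when that IoU ≥ threshold (default 0.25), inheriting its
3D label; unlinked masks start new labels, and ids are relabelled
consecutively.  Linking is one-to-one toward the past (each mask has at most
one predecessor).  **Known limitation:** very small terminal slices — e.g.
the single-voxel polar cap of an integer-radius voxelized sphere — fall
below any reasonable IoU threshold and become separate labels; this is
inherent to greedy overlap stitching, and such fragments are exactly what
the downstream volume/axis filter removes.

Per-label features: volume = voxel count × voxel volume; axis lengths =
`4·√eigenvalue` of the second-central-moment tensor computed in physical
coordinates (anisotropic spacing folds into the moments), so the
major/minor ratio equals the equivalent ellipsoid's elongation.  Filtering
keeps rows whose volume and both axis lengths lie inside closed bounds; the
bounds ship unset and must be supplied explicitly — inventing default
cut-offs would silently change downstream statistics.

## Synthetic phantoms

- **Dual-view pairs:** depth-dependent blur linear in distance from each
  view's near surface (`σ(z) = σ₀ + k·z` voxels; defaults σ₀ = 0.5,
  k = 0.06/plane), exponential attenuation (0.005/µm), optional Poisson
  noise applied after blur/attenuation and before the constant camera
  background — the camera-physics order.  The ground-truth crossover is the
  plane where the two blur widths are equal; an asymmetric blur offset
  places it anywhere.  The truth stack (`textured_phantom`) mixes smoothed
  random blobs with white texture so every plane has high-frequency content
  for the DCTS to lose under blur.
- **Bead fields:** unit-peak anisotropic Gaussians at uniform subvoxel
  positions with a 5σ border margin and a minimum separation (default 4σ).
- **Tracks:** ballistic (`r(t) = r(0) + v·t`, random unit directions) or
  Brownian (per-axis Gaussian increments, variance `2D·dt`); defaults
  D = 1 µm²/h, dt = 0.1 h, 20 steps, matching organoid-scale cell motility.
- **Ellipsoid labels:** implicit-equation voxelization; overlap is refused.

All generators are bit-reproducible per seed.  What they do **not** emulate:
striping, scattering kernels, refractive-index inhomogeneity, spatially
varying PSFs, or cell divisions/track merges.  Passing tests therefore
demonstrate correctness of the algorithms under the stated degradation
model, not performance on arbitrary real specimens.

## Problem sizes

Default test/acceptance sizes are chosen so the whole suite runs in tens of
seconds: 50-plane 64×64 dual-view pairs (20 seeds), 40×64×64 bead phantoms
for registration (10 seeds), 64×128×128 bead fields for PSF measurement,
500-track Brownian ensembles.  These sizes leave the statistical targets
(±2 planes, 0.25 voxel/0.2°, 10% of 6Dt, 5% on axis ratios) comfortably
met; larger stacks change runtime, not the algorithms.
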
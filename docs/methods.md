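# Methods

## Scope and model

`tomocoat` reimplements, at desk scale, the computational chain used to
determine a vesicle-coat structure by cryo-electron tomography and
subtomogram averaging, and to localize a substoichiometric binder by
multireference classification and difference-density analysis. Because real
tilt-series data are far too large for routine testing, every stage is
validated against a synthetic forward model with exact ground truth:

* **Leaf phantom.** The coat asymmetric unit ("leaf" — one coatomer complex
  plus two Arf1 molecules in the real system) is modelled as a handful of
  isotropic Gaussian blobs with distinct weights. Distinct weights and a
  non-planar arrangement guarantee the layout has no rotational
  self-symmetry, which makes pose recovery well-posed. An optional extra
  "GAP" blob stands in for a bound ArfGAP catalytic domain. A rendered
  atomic model (via `classify.simulate_model_density`) can replace the blob
  phantom when a more structured reference is wanted.
* **Vesicle scenes.** Triads (three C3-related leaves around an
  outward-pointing axis) are placed on spherical membranes by rejection
  sampling with a minimum angular separation (bounded at 1000 retries), a
  uniformly random azimuth per triad, and leaf axes normal to the membrane
  (an optional jitter emulates coat flexibility). The membrane is a radial
  Gaussian shell. All randomness flows from one integer seed through a named
  `numpy.random.Generator`; scenes are bit-reproducible.
* **Acquisition.** Dose-symmetric tilt ordering (0, +s, −s, −2s, +2s, …)
  over ±60° at 3° steps; a total exposure of 85 e/Å² spread uniformly over
  the tilts in acquisition order (the per-tilt frame scheduling of a real
  session is not modelled); per-series defocus drawn from −2 to −5 µm; a
  standard oscillatory CTF (300 kV, Cs 2.7 mm, 7% amplitude contrast, sign
  convention chosen so contrast is positive at low frequency);
  exposure-dependent low-pass filtering with the published critical-exposure
  constants a = 0.245, b = −1.665, c = 2.81 in Ne(k) = a·k^b + c;
  ramp-weighted back-projection about a fixed y tilt axis with linear
  interpolation (cubic optional). CTF correction is whole-image phase
  flipping: at the simulated field of view the defocus gradient across an
  image is negligible, so strip-wise correction would change nothing.

## Alignment engine

Scores are constrained cross-correlations: normalized correlations computed
only over the Fourier region sampled by both volumes (intersection of their
wedges and an optional band-pass, DC always excluded). This equals the
real-space normalized dot product of the filtered volumes by Parseval, which
is the oracle used in tests.

Rotation search is hierarchical: an initial full in-plane scan followed by a
cone of the reference z axis crossed with local in-plane spins, composed to
the right of the current pose. For each candidate rotation the translation
is read from the FFT cross-correlation peak within a shift limit.
Candidates are ranked on *parabolically interpolated* peak heights, not raw
grid values: with integer-only shift sampling, a small off-rotation can
mimic a subvoxel translation and outscore the true rotation; interpolating
the peak before ranking removes that degeneracy (observed directly during
development on noise-free phantoms).

Averaging is wedge-compensated: Fourier numerator = sum of back-rotated
particles, denominator = sum of correspondingly rotated wedge weights,
floored at 0.1·N to avoid amplifying frequencies seen by only a few
particles; uncovered frequencies are zeroed. Cn symmetry is applied by
real-space averaging of rotated copies (cubic interpolation keeps the result
rotation-invariant to ~1e-3 relative).

Iteration stops when the median angular change drops below half the finest
angular step and the median shift change below 0.5 voxel, or at
`max_iterations` (default 10); a mean CC decreasing three iterations running
triggers a divergence warning and returns the best iteration. Two half-sets
(odd/even vesicle ids — whole vesicles never straddle the split) are
processed completely independently for gold-standard validation.

Cleaning and deduplication thresholds are not universal constants; defaults
are mean − 2 SD for the CC cut and 0.8× the expected lattice spacing for the
distance cut, both surfaced in the run config and recorded in the run log.

A caveat documented deliberately: refinement against an evolving reference
determines poses only up to one global rigid transform (the gauge).
`alignment.pose_recovery_errors` removes the best common transform (chordal
mean of the per-particle discrepancy rotations) before reporting errors, and
every parameter-recovery figure in tests and the acceptance script is gauge
corrected.

## Validation

FSC uses one-Fourier-voxel shells, FSC(k) = Re Σ F₁F₂* / √(Σ|F₁|² Σ|F₂|²),
with zero-power shells flagged and reported as 0. Resolution is the first
downward crossing of the criterion (0.143 by default, 0.5 also reported),
linearly interpolated between shells; a curve that never crosses returns
Nyquist, flagged. Local resolution repeats the FSC in a soft-edged spherical
window (default 20 voxels, step 4, soft edge 3) sliding over the map, with
linear interpolation between window centers. No phase-randomization
correction for mask bias is applied — a known limitation; masks used here
are soft (cosine-tapered) to keep correlation leakage small.

Focused refinement (`local_align_and_combine`) runs one alignment pass per
soft mask and recombines as Σ(maskᵢ·avgᵢ)/Σmaskᵢ where the mask sum exceeds
1e-3, else 0 — mask-weighted averaging is our reading of "normalized within
the enclosed volume", stated here as an interpretation.

B-factor sharpening multiplies amplitudes by exp(−B·k²/4) (negative B
sharpens; default −1400 Å², magnitude capped at 1e5) followed by a low-pass
at the measured resolution.

## Classification and difference density

Multireference classification keeps refined poses fixed and scores each
particle against each reference rendered at its pose (masked,
wedge-constrained CC), assigning to the argmax with ties to the lowest class
index; class averages are re-formed each of the (default 3) iterations, and
a class that empties retains its previous average with a warning.

Model densities are mass-weighted Gaussians with σ = 0.225 × resolution (the
convention of the common model-to-map rendering tools), normalized so each
atom's grid integral equals its mass. Difference maps subtract the
least-squares amplitude-scaled model from the experimental map — the scaling
is our declared normalization, logged with each run. Segmentation thresholds
at a configurable multiple of the difference-map σ (default 1), labels
connected components (6/18/26-connectivity, default 26), and ranks by voxel
volume with centroid tie-breaks for determinism. The permutation control
(`permutation_control_volumes`) provides the null distribution of largest
component volumes under random particle relabelling; a real binder signal
must exceed it, and a binder-free control must not.

Rigid-body fitting maximizes real-space correlation between the rendered
model and the map with a derivative-free Powell search over three
rotation-vector components and three shifts, starting within the capture
range (about half a blob width); the returned score never drops below the
starting score. Cross-link screening applies the strict below-35-Å rule to
uniquely resolved atom selectors. The linker worked example is plain
arithmetic: residues × per-residue rise (3.6 Å default), 103 × 3.6 ≈ 371 Å.

## Linkage analysis

Neighbor pairs within a distance cutoff carry the relative pose of one triad
in the other's frame (`rel(i,j) = rel(j,i)^{-1}` by construction). Pairs are
clustered agglomeratively (average linkage) under a combined metric,
geodesic rotation angle in degrees plus Euclidean translation in voxels,
weighted 1°≡1 voxel by default, with each unordered pair represented by the
nearer of its two inverse-related descriptions. The four specific native
linkage geometries come from prior structural work and are deliberately not
re-derived; this module validates generic planted-class recovery instead.

## Problem sizes and numerical choices

Default desk-scale sizes, chosen as the package's own test conditions:
32-voxel particle boxes at 4 Å/voxel (leaf ~60 Å across), vesicles of 70–120
Å radius in 64–96 voxel scenes, 2–4 tomograms per run, 10–200 particles per
experiment, 5 seeds for stochastic summaries. SNR is defined as the
whole-box variance of the wedge-filtered signal over the noise variance.
Interpolation is linear except where symmetry tests need cubic; rotation
centers are `n // 2` per axis, matching the `fftshift` origin; Fourier masks
live in unshifted layout and are forced exactly Friedel-symmetric.

What passing these tests does **not** show about real data: no tilt-series
misalignment, no gold-fiducial or motion errors, no structured noise
(membrane proximity, crowding, cargo), Gaussian blobs instead of real
molecular contrast, and CTF parameters known exactly rather than estimated.
The synthetic conditions isolate the *algorithms*; absolute resolutions
reported on them are not comparable to experimental values.

## CLI

The shell entry point `tomocoat` exposes the file-level stages (simulate,
reconstruct, pick, validate, sharpen, diffmap, linkages, run-all). The
alignment, focused-refinement and classification stages operate on in-memory
particle stacks inside `run-all`; standalone use goes through the library
API, which is the intended interface for scripting.
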
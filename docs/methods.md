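# Methods

This note documents the models, estimators and numerical choices behind
`perinuc`, in the order data flows through the pipeline.

## Synthetic scenes

The generator emulates wide-field z-stack acquisition of a yeast nucleus
carrying one fluorescently tagged chromatin locus. Defaults define the study
conditions used by the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| grid | 64 × 64 × 40 voxels | field of view; 40 z-sections |
| voxel | 0.1065 × 0.1065 × 0.26 µm | xy = typical 100×/EMCCD sampling; z = acquisition spacing |
| nucleus radii | 1.3 µm (sphere) | ellipsoids supported; (4/3)πabc is the ground-truth volume |
| shell thickness | 0.1 µm | sub-resolution envelope marker |
| PSF σ_xy, σ_z | 0.13, 0.30 µm | anisotropic Gaussian blur |
| spot amplitude | 200 photons | peak-SNR ≈ 13 over background |
| membrane amplitude | 150 photons | shell peak above background |
| background, read noise | 10, 2 photons | camera floor |

The membrane channel is the indicator of a thin shell around the ellipsoid
surface convolved with the PSF; the locus channel is a single 3D Gaussian at
the exact continuous spot position. Noise is Poisson on the expected photon
count, then additive Gaussian read noise; both are independently switchable
so noiseless stacks serve as exact oracles. The spot's scaled depth
s ∈ [0, 1] is placed along a (seeded) direction; ground truth records the
exact position, volume, effective radius and the analytic nearest-surface
depth (closed-form for spheres, bracketed root-finding of the ellipsoid
Lagrange condition otherwise).

Cohort samplers: `uniform_volume` draws positions uniformly in the unit ball
(radius U^{1/3}); `periphery_biased` draws s from an exponential of scale 0.1
truncated to [0, 1] (first-shell mass ≈ 0.63, a strongly peripheral locus).
The biased sampler is a test harness, not a mechanistic model of tethering.

What the generator does *not* emulate: EM-gain/register statistics, chromatic
aberration, multiple spots per cell, out-of-focus haze from neighboring
cells, and non-ellipsoidal (e.g. dividing) nuclei. Passing tests therefore
demonstrate correctness of the estimators under controlled optics, not
robustness to every artifact of real micrographs.

## Spot localization

Candidates come from the maximum-intensity z-projection: pixels above a
robust threshold (median + 5 × 1.4826·MAD of the projection) that are local
maxima within a 1.5-pixel radius; when two candidates fall within the radius
the brighter wins, exact ties resolving to the lowest row-major index. Around
each candidate a 7 × 7 × 9 voxel window (x, y, z; ≥ ±3σ of the default PSF)
is cut from the raw stack and an axis-aligned 3D Gaussian with
σ_x = σ_y ≠ σ_z plus a constant offset is fitted by trust-region least
squares. Initialization: intensity-weighted centroid, window minimum as
offset, max − min as amplitude, PSF priors as widths; bounds keep the center
inside the window and widths in [0.5, 4] × priors; convergence at relative
objective decrease < 1e-10 or 500 function evaluations. Non-converged fits
are dropped (with a logged reason) rather than clamped — a forced fit biases
the position, a dropped one only reduces n. On the default noisy scene the
localization RMSE is ≈ 0.03 voxel laterally and axially; noiseless fits are
exact to optimizer precision.

## Envelope reconstruction

An icosphere (subdivision 3, 642 vertices) is seeded from the membrane
channel: Otsu threshold of the maximum projection → largest connected
component → radius r₀ = √(A/π) and xy centroid. The z center is the
background-subtracted intensity-weighted centroid over slices — a hollow
shell spreads per-slice intensity nearly uniformly across the nucleus, so
the single brightest slice is an unstable center estimate (observed errors
up to half a radius), while the centroid is robust.

Vertices then descend the total energy

E = λ_bend · Σ_v ‖v − mean(N(v))‖²/h² − λ_img · (1/|V|) Σ_v Î(v),

with h the mean edge length, Î the min–max-normalized membrane intensity
trilinearly interpolated at v (0 outside the stack), and defaults
λ_bend = 1, λ_img = 10 so the image term dominates at the shell rim.
Optimization is plain gradient descent (analytic gradient; the image-term
gradient interpolates precomputed ∇Î volumes) with backtracking line search:
the step is halved on any energy increase and gently regrown after accepted
steps, making the energy non-increasing and the whole procedure
deterministic. Termination: relative energy change < 1e-6 or accepted
displacement < 1e-4 µm sustained for 5 iterations, or 500 iterations.
The `converged` flag reports whether the final mesh is a valid closed
surface (watertight, consistently wound, positive volume); iteration count
and final energy are kept as diagnostics.

**PSF-curvature bias correction.** The intensity ridge of a blurred thin
shell does not sit on the true surface: a spherical shell of radius R
convolved with a Gaussian of width σ peaks at R − σ²/R to first order. An
intensity-seeking surface therefore lands inside the envelope, worst for
small nuclei and along z (σ_z = 0.30 µm ⇒ a −12 % volume bias at R = 1 µm).
After descent each vertex is pushed outward along its normal by σ_n²/r,
where σ_n² is the PSF variance along the normal and r the local distance to
the mesh centroid (a good curvature proxy for near-spherical shapes). With
the correction, noiseless volume errors are ≤ 2.4 % across radii 1.0–1.6 µm
and noisy errors ≈ 2–10 %. The correction is exposed
(`EnergyConfig.correct_psf_bias`) and uses the same PSF priors as the spot
fitter.

Derived geometry: volume from signed tetrahedra of the closed mesh
(`trimesh`), effective radius (3V/4π)^{1/3}, and exact point-to-surface
distance as the minimum over all faces of the point–triangle distance
(vectorized region classification handling vertex/edge/interior cases),
with inside/outside from the sign of the generalized winding number — robust
arbitrarily close to the surface, unlike ray casting.

## Radial density

Each usable cell contributes s = d/R_eff, where d is the spot-to-surface
distance; spots outside the mesh get s < 0 and are excluded *and counted*,
never clamped — clamping would inflate the peripheral bin, the analysis's
key readout. Depths are pooled and binned into 1/w shells (w = 0.1; s = 1
closes into the innermost bin), and

f = p / (4π r_mid² w),  σ_f = √c / (N · 4π · (1 − s_mid)² · w),

with r evaluated at the bin midpoint. Two consequences of that convention
are worth knowing:

* σ_f/f = 1/√c exactly in every occupied bin, and σ_f agrees with a
  cell-level bootstrap to within ~20 % wherever c ≳ 10 (the small residual
  is the binomial √(1−p) factor the Poisson form ignores).
* The innermost shell's midpoint volume 4π(0.05)²w understates its exact
  scaled volume (4π/3)(0.1)³ by a third, so a perfectly uniform distribution
  reads f ≈ 0.318 there instead of 3/4π ≈ 0.239, on top of the amplified
  count noise of a nearly empty bin. Values are reported as the estimator
  defines them; comparisons against uniformity in the test suite use the
  exact per-bin expectation for that single bin.

## Peak proximity

Distances are boundary-to-boundary gaps between interval bodies (0-based
half-open internally; GFF3 converted at the I/O boundary): overlap or
book-ending ⇒ 0, different chromosomes ⇒ ∞, strand ignored, "within 600 bp"
inclusive. The implementation is an exact per-chromosome sorted sweep
(prefix maximum of peak ends + binary search on starts), verified against an
all-pairs brute force. The feature/peak fixture generator plants an exact
fraction of features within the threshold and keeps all others ≥ 2× the
threshold from every peak, so recovered fractions are exact by construction.

## Rates

The per-culture "rate" is the raw resistant-colony frequency: both counts
rescaled to the undiluted culture, then ratioed —
(sel/dil_sel)/(perm/dil_perm). It is deliberately not a Luria–Delbrück
mutation-rate estimate. Zero selective colonies give rate 0 with a censoring
flag (no pseudo-count); zero permissive colonies are an error since the
culture size is unknown. Fold change divides each rate by the wild-type
group's mean; ln fold change is taken where the fold change is positive,
with zero-rate samples flagged and excluded from the log. Note the estimator
carries a small positive bias of order 1/E[permissive count] (Jensen's
inequality on the count ratio), ≈ 11 % at the default 10 permissive
colonies; it largely cancels in fold changes between genotypes plated the
same way. Downstream hypothesis tests are intentionally out of scope; the
module exports tidy per-sample tables for external statistics.

## Problem sizes and determinism

The acceptance script and test suite run: sphere recovery at radii 1.0, 1.2,
1.4, 1.6 µm (noiseless and noisy); 100 noisy spot localizations; analytic
density checks at n = 10⁵ samples and a 2000-replicate bootstrap at n = 10³;
one full-pipeline contrast of 200 uniform vs 200 periphery-biased nuclei
(the flatness of uniform cohorts across 20 seeded replicates is checked at
the analytic-sampling level, where the estimator itself — not the imaging —
is under test); 100 random proximity fixtures; and 2 × 50 simulated cultures.
Every stochastic stage takes an explicit seed, and per-cell seeds derive
deterministically from the global one, so identical configurations produce
byte-identical outputs.

## Known limitations

* The envelope model assumes one near-ellipsoidal nucleus per stack; no
  topology changes, remeshing, or dividing-nucleus shapes.
* The PSF-curvature correction is first order and uses configured PSF priors;
  a strongly miscalibrated PSF propagates into a radial bias of the surface.
* Coarse z sampling (0.26 µm vs σ_z = 0.30 µm) leaves residual surface error
  near the poles of order 0.05–0.1 µm, visible as scatter in recovered s.
* The proximity statistic reports raw fractions only (no enrichment test),
  matching how such genome-wide prevalences are typically quoted.
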
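# Methods

This note documents the models, parameter choices, and numerical
conventions behind `bonevasc`, and what the synthetic-data validation does
and does not demonstrate about real data.

## Imaging model and phase retrieval

Propagation-based phase-contrast imaging is modeled in the linearized
homogeneous-object (single-material) regime. A projected thickness map
T(x, y) of a material with refractive index n = 1 − δ + iβ produces, after
free-space propagation over a distance z, the flat-normalized intensity

    I_z/I₀ = IFT[ FT[exp(−µT)] · (1 + (zδ/µ)·4π²|u|²) ],

with µ = 4πβ/λ and u the spatial frequency in cycles/µm. Phase retrieval
divides by the same filter and takes −ln(·)/µ. Because forward and inverse
use the identical pointwise filter, the pair is an exact inverse on the
periodic FFT domain regardless of the object, up to floating point; the
round-trip tests use `pad=False` to exercise exactly this property
(worst-case relative error ~1e−12). The default `pad=True` reflect-pads to
the next power of two before filtering to suppress wrap-around on real
(non-periodic) projections; padding makes the pair approximately inverse
near borders, which is the right trade-off for measured data but not for
testing exactness.

Defaults: 24 keV (λ = 0.517 Å), z = 5 cm, 0.64 µm pixels — a standard
synchrotron microtomography configuration. δ = 1e−7 and β = 1e−10 are
soft-tissue-scale values at this energy; only the ratio δ/µ enters the
filter, and both are configurable per run. Retrieval clips the filtered
intensity at 1e−12 before the log so that heavily noisy inputs degrade
gracefully instead of producing NaNs.

Tomography uses scikit-image's parallel-beam `radon`/`iradon`
(`circle=False`, linear interpolation, ramp filter by default with optional
Hann apodization). The simulated acquisition covers 0–180°, sufficient for
parallel beam; 360° inputs are accepted by the reconstruction (angles are
used as given). Angular coverage below 180° (span plus one median step) is
rejected.

## Scaffold/vessel phantom

The phantom emulates a porous ceramic scaffold cube containing tubular
vessel trees, sampled at 0.64 µm/voxel (default 256³ ≈ 164 µm cube — a
desk-scale stand-in for a millimetre-scale analysis volume; every statistic
downstream is per-depth and hence scale-free). Vessels grow from an entry
face as a persistent random walk (step 2 voxels, Gaussian direction jitter
with a small bias along the entry axis), branch as a Poisson process per
unit length (default 0.02/µm), and children shrink by a taper factor
(default 0.85, clipped at the minimum class diameter) and deflect by a
random 20–60° angle. Root diameters are drawn from the upper part of the
10–20 µm class span so trees show the large-parent/small-children structure
of real vascular trees. The scaffold phase is a solid matrix minus
overlapping spherical pores carved until the target volume fraction is
reached; it is geometric only (no mineral phases, no bone growth).

The continuous centerlines are retained as ground truth. Voxelization marks
every voxel whose center lies within the local radius of a centerline
segment (exact capsule test per segment), so the voxel count of an
unbranched tube matches the analytic πr²L within discretization error
(measured ≈ 1%, bounded at 15% in tests). `truth_depth_profile` counts
centerline crossings of each slice-center plane with the analytic diameter
— the geometric twin of the voxel-based per-slice counting, and exactly
equal to it for unbranched axis-aligned tubes.

A `direction_jitter = 0` setting produces perfectly straight axis-aligned
tubes; this is what makes the exact-equality oracle meaningful. With jitter
on, tubes cross slices obliquely and the equivalent diameter inflates by
~1/√cos(tilt), a documented measurement property rather than a bug.

## Vessel quantification

Segmentation: global threshold (fixed value or Otsu; a constant volume
yields an empty mask), morphological opening with a radius-1 ball, removal
of 26-connected components below a voxel-count floor. Per-slice counting
uses 8-connectivity in 2D and the equivalent circular diameter
d = 2√(A/π). Class intervals are half-open, [10, 15) and [15, 20] µm, so a
boundary 15 µm vessel is "large"; components outside [10, 20] µm count in
the total but in neither class.

Section weights default to the circle area at the class-midpoint diameter:
π(12.5/2)² = 122.7 → reported 123 µm², π(17.5/2)² = 240.5 → 240 µm²
(nearest integer below 200 µm², two significant figures above; internal
computation keeps full precision). The measured-average interpretation of
these weights is equally consistent with the printed values; the midpoint
interpretation was adopted because it needs no data.

The vascularization factor is the section-weighted depth integral of the
class counts divided by a normalization depth. The normalization defaults
to the analyzed depth of the profile; `PAPER_DEPTH_NORM_UM` (1400 µm) is
provided for comparisons that normalize all samples over a fixed analysis
cube even when vessels span less. VF is linear in the counts and invariant
under slice-thickness refinement of a piecewise-constant profile.

Skeletonization wraps scikit-image's 3D thinning and converts the voxel
skeleton to a graph: clusters of voxels with ≠ 2 neighbors become nodes
(endpoints/junctions by graph degree), slab chains become edges with
Euclidean path lengths, closed loops with no branch voxels become
self-loop edges anchored on the loop, and the cycle count is the circuit
rank E − V + C. "Number of branches" is the edge count after iteratively
pruning endpoint-terminated spurs shorter than a cutoff (default 5 µm,
suppressing thinning artifacts at tube caps); junction-to-junction
re-merging after pruning is deliberately not performed, and the convention
is stated here because branch counts depend on it. Local radii are the
Euclidean distance transform of the source mask sampled at skeleton
voxels. One known limitation: thinning of a mask with perfect
between-voxel mirror symmetry (e.g. an analytically centered cylinder of
even voxel diameter) is degenerate in the underlying thinning
implementation; real segmented masks do not have this symmetry.

## Diffraction analysis

Detector mapping follows q = 4π sin(θ)/λ with 2θ = atan(r/L) per pixel and
Φ = atan2 of the pixel offset, counterclockwise from the detector +x axis;
orientation angles are reported mod 180°. Radial and azimuthal integration
are equal-width histogram means; empty bins are flagged and excluded from
fits. A (q, Φ) rebinning helper conserves total counts exactly.

The equatorial collagen peak is fitted as a Gaussian on either a
second-order polynomial or a power-law background (both appear in practice
for this signal; poly2 is the default and neither is privileged — select by
config). Initialization: peak position from the argmax of the 3-bin
median-filtered window, σ₀ = window width/6, background from the outer
quarter of the window's bins. Non-convergence or a window whose maximum
sits on its edge produces a flagged result with diagnostics rather than an
exception. The lateral spacing is stored as D = 2π/q_c, so D·q_c = 2π holds
to the last bit by construction.

The azimuthal profile is fitted as a constant plus two wrapped Gaussians
with shared amplitude and width, 180° apart (equatorial symmetry). The
orientation degree is A_Φ/A_BKG with A_Φ = 2·amp·σ√(2π) (wrapping
redistributes but does not change the total peak area) and
A_BKG = c·360°. A profile with relative variation below 1e−3 is reported
as degree 0 directly — the peak width is unidentifiable on flat data. A
negative fitted background flags the result.

The pattern simulator places background(q) plus a Gaussian ring at q_c
modulated by (1 − f) + f·wrapped-Gaussian-pair(Φ) with aligned fraction f,
and optional seeded Poisson noise. The default simulated detector is
scaled down (256 px of 50 µm at 40 mm, λ = 0.0976 nm) so the collagen ring
at 5.6 nm⁻¹ sits well inside coverage with a q range of ~0–10 nm⁻¹;
real-geometry values can be passed instead, and the q-mapping is verified
against hand arithmetic at metre-scale distances. An analytic oracle
(`expected_orientation_degree`) integrates the closed-form model over the
q window to predict the degree a ring integration should see,
independently of the fitting code. Note the measured degree is a property
of the windowed azimuthal profile (radial background included in its
constant term), so it tracks, but does not numerically equal, the
generator's aligned fraction; tests therefore check the analytic oracle
and monotonicity, not naive equality.

Scan grids derive per-position noise seeds from the base seed; collagen
maps mask positions whose peak or orientation fit is flagged or whose peak
area is consistent with zero.

## Problem sizes and determinism

The validation suite and the acceptance script use 48³–96³ phantoms with
80–200 projection angles, 128²-pixel simulated patterns, and 100-pattern
noise ensembles — sizes chosen so the full chain (including 200 radon/FBP
transforms per volume) completes in seconds while keeping discretization
effects representative. All stochastic stages consume a single integer
seed; identical configurations reproduce outputs bit-for-bit, which the
pipeline manifests verify via SHA-256 checksums of every emitted file.

## What passing tests show — and what they do not

The phantoms establish correctness of the measurement chain (retrieval is
the exact inverse of its forward model; counting equals the analytic
oracle; fits recover known parameters under Poisson noise). They do not
emulate reconstruction artifacts of real beamline data (ring artifacts,
flat-field drift, partial-volume mixing of stains), scaffold mineral
chemistry, or vessel-collagen ambiguity; on real volumes the segmentation
threshold and the minimum-component floor remain the operator's
responsibility, and the per-sample numbers inherit that choice.
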
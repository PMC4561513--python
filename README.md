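# bonevasc

Quantitative analysis of 3D micro-vascular networks and collagen
organization in engineered-bone scaffolds, as imaged by propagation-based
X-ray phase-contrast micro-tomography (XRPCµT) and scanning X-ray
micro-diffraction (XRµD).

When a porous ceramic scaffold seeded with bone marrow stromal cells is
implanted in vivo, the success of bone regeneration hinges on how well a
micro-vascular network (vessels of roughly 10–20 µm diameter) penetrates the
construct. `bonevasc` provides a tested, end-to-end re-implementation of the
computational chain needed to quantify that network from synchrotron data,
plus the diffraction analysis that distinguishes collagen-fiber bundles from
capillaries — along with a synthetic-data module that generates phantoms and
diffraction patterns with analytic ground truth, so every stage can be
validated without any experimental download.

## What it computes

**Tomography side** (`recon`, `vessels`, `skeleton`):

- Single-distance phase retrieval for a homogeneous object
  (n = 1 − δ + iβ, µ = 4πβ/λ):
  `T = −(1/µ) ln IFT[ FT[I/I₀] / (1 + (zδ/µ)·4π²|u|²) ]`,
  paired with its exact forward model for round-trip validation, and
  parallel-beam filtered back projection (ramp/Hann) for slice
  reconstruction.
- Vessel segmentation (global/Otsu threshold, morphological cleanup) and
  per-slice cross-section counting: each 2D connected component of area A
  gets an equivalent diameter d = 2√(A/π) and is classed *small*
  (10 ≤ d < 15 µm, count V_m) or *large* (15 ≤ d ≤ 20 µm, count V_M).
- 3D centerline skeletonization with branch-graph extraction (endpoints,
  junctions, branch counts with spur pruning, cycles via the circuit rank).
- The vascularization factor, a flow-capacity proxy assuming flow ∝ vessel
  section:
  `VF = [ s_m ∫V_m(z)dz + s_M ∫V_M(z)dz ] / Z_norm`,
  with section weights s_m ≈ 123 µm² and s_M ≈ 240 µm² (circle areas at the
  class-midpoint diameters 12.5 and 17.5 µm).

**Diffraction side** (`diffraction`, `diffsim`):

- Detector q-mapping (q = 4π sin θ / λ, 2θ = atan(r/L)), radial integration
  to I(q) and azimuthal integration to I(Φ) within a window around the
  collagen equatorial ring at q ≈ 5.6 nm⁻¹.
- Equatorial peak fit (Gaussian + poly2 or power-law background) giving the
  collagen lateral spacing D = 2π/q_c ≈ 1.12 nm and the peak area
  (collagen amount); azimuthal fit (constant + wrapped Gaussian pair 180°
  apart) giving the orientation angle and the orientation degree
  A_Φ/A_BKG; per-scan-position assembly into amount/angle/degree maps with
  vector-plot export.

## Worked example

```bash
bonevasc demo --outdir demo_out --seed 1
```

runs both workflows on a small synthetic sample (64³-voxel phantom with two
vessel trees at 0.64 µm/voxel; 3×3 scan of simulated diffraction patterns)
and prints `tomography: ok; diffraction: ok`. The emitted
`demo_out/summary.json` reads:

```json
{
  "max_section_um2": 223.6416,
  "min_diameter_um": 10.13603604729847,
  "n_branches": 2,
  "total_v_small": 23,
  "total_v_large": 80,
  "vf": 344.203125
}
```

i.e. the largest vessel cross-section in any slice is ~224 µm², the smallest
classed vessel ~10.1 µm in diameter, the skeleton has 2 branches ≥ 5 µm, and
summing the per-slice counts (23 small-vessel and 80 large-vessel slice
crossings over the 41 µm analyzed depth) with the 123/240 µm² weights gives
VF ≈ 344 µm². `demo_out/depth_profile.csv` holds the per-slice counts
(slice, depth_um, v_small, v_large, v_total) and
`demo_out/collagen_vectors.csv` the per-position collagen amount,
orientation angle and degree recovered from the simulated scan.

The same stages are scriptable (`bonevasc phantom/retrieve/reconstruct/
quantify/diffract`) and available as a library:

```python
from bonevasc import (PhantomSpec, generate_phantom, segment_vessels,
                      per_slice_counts, vascularization_factor)

vol, truth = generate_phantom(PhantomSpec(shape_voxels=(96, 96, 96)))
mask = segment_vessels((vol.labels == 2).astype(float), 0.64, threshold=0.5)
profile = per_slice_counts(mask)
print(vascularization_factor(profile))
```

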
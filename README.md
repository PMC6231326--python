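# mechquant

Quantification toolkit for mechanobiology imaging assays. It implements, as a
tested reusable library with a CLI, three measurements that labs typically
re-build ad hoc around high-content microscopes:

1. **Multiscale nematic-tensor anisotropy** of cytoskeletal fiber images
   (phalloidin/actin, collagen second-harmonic, …) — a score in [0, 1] for how
   parallel the fibers in an image are, aggregated over image patches at many
   scales.
2. **Nucleocytoplasmic (N:C) ratio quantification** of a transcription-factor
   marker (e.g. YAP immunofluorescence) per cell: nucleus segmentation from a
   DNA (Hoechst) channel, quality-control filtering of mitotic, aberrant and
   border-touching nuclei, a fixed-width perinuclear ring as the cytosolic
   region, and categorical localization calls (N / C / N-C).
3. **siRNA-screen statistics**: per-well Z-scores against non-targeting
   control wells with replicate averaging and strict hit calling, genotype
   specificity partitioning, Fisher exact gene-set enrichment, dual-luciferase
   normalization, and collagen gel-contraction fold changes.

A fourth module generates synthetic inputs with known ground truth — fibrous
textures with a planted orientation distribution, multicell fields with a
planted N:C ratio and planted QC defects, and screen plates with planted hit
effects — so every measurement is validated by parameter recovery.

## The measurements

**Fiber anisotropy.** At each pixel the intensity gradient `(gx, gy)` is
rotated by 90° to give the local fiber direction θ (defined modulo π). A pixel
set is summarized by the mean nematic tensor — the traceless symmetric matrix
`[[c, s], [s, −c]]/2` with `c = ⟨cos 2θ⟩`, `s = ⟨sin 2θ⟩` (weighted means) —
whose eigenvalue difference

    score = λ₁ − λ₂ = √(c² + s²)

is the nematic order parameter: 0 for an isotropic texture, 1 for perfectly
parallel fibers. The multiscale score tiles the image into N×N patches for
every N in {2ⁱ} ∪ {3ⁱ} (down to a minimum patch side of 10 px), scores each
patch with enough oriented pixels, assigns every pixel the mean score of the
processed patches containing it, and averages over pixels. Analysis can be
restricted to a segmentation mask.

**N:C ratio.** Nuclei are segmented from the DNA channel (Gaussian smoothing,
Otsu threshold, hole filling, distance-transform watershed, per-nucleus
half-max boundary refinement). QC removes nuclei that are over-bright
(candidate mitotic), insufficiently round (4πA/P² below threshold), out of an
area range, or touching the image border. The cytosolic reference is a 4-px
ring grown radially from the nuclear border (conflicts between neighboring
cells resolved by nearest nucleus), and

    nc_ratio = mean marker over nucleus / mean marker over ring.

Cells are called predominantly nuclear (N) when `nc_ratio > 1 + δ`,
predominantly cytosolic (C) when `nc_ratio < 1/(1 + δ)`, and evenly
distributed (NC) otherwise (δ = 0.2 by default). A nuclear-to-total readout
(summed nuclear marker over summed whole-cell marker) is also computed.

**Screen Z-scores.** Per plate and replicate, control wells define the
normalization and each siRNA's well mean `x` is scored as

    Z = (x − control mean) / control SD        (sample SD, n − 1),

the replicate Z's are averaged, and a hit requires `|mean Z|` strictly above
2.5. Fisher enrichment p-values are exact hypergeometric tails computed from
log-factorials.

## Worked example

```python
import numpy as np
from mechquant import (FiberSpec, CellFieldSpec, ScalePlan, generate_fibers,
                       generate_cell_field, multiscale_anisotropy,
                       quantify_field)

# fibers with von Mises concentration kappa = 4 around the horizontal
img, truth = generate_fibers(FiberSpec(height=512, width=512, n_fibers=300,
                                       kappa=4.0, seed=42))
whole = multiscale_anisotropy(img, plan=ScalePlan((1,)), weighting="grad2")
multi = multiscale_anisotropy(img, weighting="grad2")
print(f"planted order parameter: {truth:.4f}")
print(f"whole-image anisotropy:  {whole.global_score:.4f}")
print(f"multiscale anisotropy:   {multi.global_score:.4f}")

# a 50-cell field with a planted nuclear:cytosolic marker ratio of 2
hoechst, marker, _ = generate_cell_field(
    CellFieldSpec(n_cells=50, nc_ratio_true=2.0, noise_cv=0.1, seed=42))
records, cells = quantify_field(hoechst, marker)
ratios = [c.nc_ratio for c in cells if np.isfinite(c.nc_ratio)]
print(f"cells measured: {len(cells)}/{len(records)}; "
      f"median N:C = {np.median(ratios):.3f}")
```

prints

```
planted order parameter: 0.8677
whole-image anisotropy:  0.8478
multiscale anisotropy:   0.8523
cells measured: 50/50; median N:C = 1.997
```

The whole-image anisotropy recovers the planted order parameter of the 300
sampled fiber angles to within ~0.02; the multiscale score is slightly higher
because small patches see locally aligned fiber segments. The median measured
N:C ratio recovers the planted ratio of 2 within 0.2%.

The same operations are available from the shell:

```
mechquant simulate fibers --seed 42 --out sim/
mechquant anisotropy --image sim/fibers.tif --out aniso.csv
mechquant enrich --table 3,1,1,3          # odds_ratio=9 p_value=0.242857
```

Every CLI run writes a JSON manifest (inputs, digests, configuration, seed)
next to its output.

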
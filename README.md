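# mitomorph

3D morphometry of hair-cell mitochondrial networks along the tonotopic axis
of the developing chick cochlea — as a tested, reusable Python pipeline.

Auditory hair cells (HCs) in the chick basilar papilla are ordered by sound
frequency, and their mitochondrial architecture diverges along that axis
during development: high-frequency (proximal) HCs grow denser, more fused
supranuclear networks than low-frequency (distal) HCs.  Quantifying this
from live TMRM-loaded confocal stacks takes a chain of image processing,
trainable voxel segmentation, skeleton analysis, stereology and multivariate
statistics.  `mitomorph` implements that chain end to end and — because raw
imaging data of this kind are rarely redistributable — ships a synthetic
ground-truth generator so every stage is benchmarked against an exact
answer key.

## What it computes

For each segmented hair cell the pipeline measures **eight skeleton-based
shape descriptors** of the supranuclear mitochondrial network:

| descriptor | definition |
|---|---|
| avg / s.d. / max branch thickness | per-branch mean of the local-thickness map (largest inscribed-sphere diameter), µm |
| avg / max branch length | per-branch skeleton path length (steps of 1, √2, √3 × voxel size), µm |
| longest shortest path | graph diameter of the skeleton network, µm |
| Euclidean distance | mean straight-line separation of branch endpoints (tortuosity proxy), µm |
| branch aspect ratio | mean per-branch path length / mean thickness |

plus the **network volume** (foreground voxels × voxel volume, µm³), which
is reported alongside but excluded from the descriptor vector.  Cells are
compared with a standardized PCA of the eight descriptors, 95% group
confidence ellipses in PC1–PC2 and out-of-sample projection (e.g. fibroblast
mitochondria onto hair-cell axes), with two-way ANOVA / unpaired t /
Kruskal–Wallis group tests and Sidak-adjusted contrasts
(p' = 1 − (1 − p)^m).

Cell-scale measurements follow the same protocols used on real tissue:

- **Cavalieri stereology** for cell volume: cross-sectional areas annotated
  on every fifth 0.18 µm optical section (0.9 µm interval); each sampled
  area × 0.9 µm is one volume segment, so the per-section multiplier is 5.
- **Lumenal surface / nuclear area** from traced polygons (shoelace formula)
  within a 50 µm × 50 µm analysis ROI, counted by centroid.
- **Mitochondrial area** on the slice just above the nuclear apex: the
  brightest 65% of the ROI's fluorescence histogram.
- **Mean TMRM intensity** in a mitochondrial mask as a ΔΨm proxy.

## Pipeline stages

```
synth       tubular networks with known branch graph + radii, Gaussian-PSF
            blur, Poisson/Gaussian noise, background gradients; cell
            phantoms with closed-form volumes; apical polygon mosaics
preprocess  isotropic resampling → rolling-ball background subtraction
            (50 px) → unsharp mask → non-local means → difference of
            Gaussians (σ 2–4 px), with full provenance
segment     random forest over a multiscale voxel feature stack, trained
            from sparse labels on a single annotated slice; binarization
            and per-cell ROI cropping
skeleton    Lee-style 3D thinning, branch-graph tracing (26-connectivity),
            spur pruning, local thickness, the eight descriptors
metrics     stereology register, polygon areas, histogram-fraction
            threshold, mean intensity
stats       standardized PCA, confidence ellipses, projection, group tests
pipeline    YAML config → OME-TIFF/CSV in, tidy CSV + JSON manifest out
```

## Worked example

```python
import numpy as np
from mitomorph import synth, measure_mask, BinaryMask

# one synthetic hair-cell mitochondrial network with known truth
image, truth = synth.make_network_cell(seed=3, n_branches=5)
print(f"true mean branch length : {truth.true_branch_lengths.mean():.2f} um")
print(f"true mean diameter      : {truth.true_branch_diameters.mean():.2f} um")
print(f"true network volume     : {truth.true_network_volume:.2f} um^3")

# measure the truth mask directly (no imaging noise)
mask = BinaryMask(truth.true_mask, truth.voxel_spacing)
m = measure_mask(mask)
print(f"measured avg thickness  : {m.avg_branch_thickness:.2f} um")
print(f"longest shortest path   : {m.longest_shortest_path:.2f} um")
print(f"network volume          : {m.network_volume:.2f} um^3")
```

prints

```
true mean branch length : 3.34 um
true mean diameter      : 0.57 um
true network volume     : 4.29 um^3
measured avg thickness  : 0.57 um
longest shortest path   : 12.86 um
network volume          : 4.29 um^3
```

The measured thickness recovers the generator's true mean tube diameter
exactly here, and the network volume matches because both count foreground
voxels.  The longest shortest path (12.86 µm) is the diameter of the whole
skeleton graph — this particular random network happens to be path-like, so
it approaches the summed branch lengths.

The same works from the shell:

```bash
mitomorph synth network --seed 3 --n-branches 4 --out out/net
mitomorph synth phantom --radius 4 --out out/ph     # volume 268.08 µm³
mitomorph metrics --areas out/ph/section_areas.csv  # multiplier 5; ≈266 µm³
mitomorph run --config run_config.yaml              # end-to-end benchmark
```

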
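# perinuc

Quantitative analysis of where tagged gene loci sit inside the nucleus — and
of the genomic and genetic correlates of that position.

In fission yeast (and many other systems), repetitive protein-coding genes
are tethered to the nuclear periphery, and that compartmentalization affects
their genetic stability. Measuring this requires several pieces of machinery
that `perinuc` provides as a single tested package:

* **Synthetic microscopy** (`perinuc.synthetic`) — ground-truthed two-channel
  z-stacks of a nucleus: a thin bright envelope shell in a membrane channel
  and a single diffraction-limited locus spot, with PSF blur, Poisson shot
  noise and Gaussian read noise. Every downstream stage is testable against
  exact ground truth without any external download.
* **Sub-voxel spot localization** (`perinuc.spots`) — maximum-intensity
  projection, robust local-maximum candidate detection, then least-squares
  fitting of an axis-aligned anisotropic 3D Gaussian
  (σ_x = σ_y ≠ σ_z) to the raw z-stack.
* **Nuclear envelope reconstruction** (`perinuc.envelope`) — an icosphere
  deformed by gradient descent on E = λ_bend·E_bend + λ_img·E_img (umbrella
  bending energy plus an image term attracting vertices to bright membrane
  voxels), yielding a closed triangulated surface, its volume V and the
  effective radius R_eff = (3V/4π)^{1/3}, plus exact point-to-surface
  distances.
* **Radial probability density** (`perinuc.density`) — each cell's scaled
  depth *s* = (distance from spot to nearest envelope point) / R_eff is pooled
  over a cohort and binned into concentric shells of width *w* = 0.1. The
  per-shell probability *p* = c/N becomes the dimensionless density

  &nbsp;&nbsp;&nbsp;&nbsp;f = p / (4π r² w), &nbsp; r = 1 − s,

  with the Poisson counting uncertainty σ_f = √c / (N·4π·(1−s)²·w), so
  σ_f/f = 1/√c. A uniform-in-volume distribution has f = 3/4π ≈ 0.2387 in
  these units; peripheral enrichment shows up as excess f at small s.
* **Peak proximity** (`perinuc.proximity`) — for a set of genomic features
  vs a set of binding peaks (BED/GFF3), the per-feature nearest-peak distance
  and the fraction of features with a peak within a base-pair threshold
  (default 600 bp, inclusive, strandless, overlap = 0).
* **Fluctuation-assay rates** (`perinuc.rates`) — per-culture event rates
  from selective/permissive colony counts and their plating dilutions,
  fold changes versus the wild-type mean rate, and natural-log fold changes
  as tidy per-sample tables.

The cohort-level analysis is wrapped statsmodels-style:
`LocusPositionModel(stacks).fit()` returns a `LocusPositionResults` with the
per-cell table, the pooled density with error bars, exclusion accounting and
a `summary()`.

## Worked example

Render a seeded cohort of 40 synthetic nuclei whose locus is biased toward
the periphery, run the full pipeline (localize → reconstruct → scale →
density) and print the summary:

```python
from perinuc import LocusPositionModel

model = LocusPositionModel.from_synthetic(
    40, mode="periphery_biased", depth_scale=0.1, seed=1
)
results = model.fit()
print(results.summary())
```

```
Locus position analysis
====================================================
cells analyzed                40
cells used                    38
excluded (spot_outside_nucleus  )     2
median scaled depth s      0.076
median nuclear volume      9.312 um^3

radial density f(s) with Poisson error bars:
       s bin     c       p        f  sigma_f
[0.00,0.10)    22  0.5789   0.5105   0.1088
[0.10,0.20)    11  0.2895   0.3188   0.0961
[0.20,0.30)     3  0.0789   0.1117   0.0645
[0.30,0.40)     2  0.0526   0.0991   0.0701
[0.40,0.50)     0  0.0000   0.0000   0.0000
...
```

Reading the output: 38 of 40 cells produced a usable (spot, nucleus) pair —
two spots landed marginally outside the reconstructed surface and are
excluded rather than clamped. The density in the outermost shell
(s ∈ [0, 0.1), f = 0.51 ± 0.11) is more than twice the uniform expectation
3/4π ≈ 0.24 while the nuclear interior (s > 0.4) is empty: the cohort's
peripheral bias is recovered. `results.plot_density()` draws f vs s with the
Poisson error bars.

The same stages are scriptable from the shell:

```sh
perinuc all --cohort periphery -n 40 --seed 1 --outdir run1
perinuc proximity --features genes.bed --peaks peaks.bed --threshold 600
perinuc rates --counts plating.csv --wt-label WT
```

Each run writes CSV tables plus a JSON manifest recording the configuration,
seeds and per-stage exclusion counts.

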
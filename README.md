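# phasepaint

Virtual fluorescent painting and phenotyping of 2.5D intestinal organoids
from label-free phase-contrast images.

## Who this is for

Organoid phenotyping usually requires immunofluorescent staining — slow,
costly, and incompatible with continuous live imaging. For 2.5D intestinal
organoids (grown on soft hydrogel so the crypt-villus architecture is
presented in a near-planar form), the key phenotypes live in three stains:
a nuclear stain (crypts have densely packed nuclei), an LGR5 reporter
(intestinal stem cells, restricted to crypts), and UEA-I lectin (secretory
cells, as dot-like puncta). `phasepaint` is for groups who image such
organoids in phase contrast and want those three channels — and the
phenotypes computed from them — without staining every plate.

## What it computes

The core is a segmentation-informed generative model. Fluorescent training
targets are binarized into masks y; an attention U-Net F maps a phase tile
x to per-pixel probabilities ŷ = F(x) and is trained with a combined
focal + Dice objective

    L = L_FL + L_DICE,
    L_FL   = −mean_i[(1−ŷ_i)^γ y_i log ŷ_i + ŷ_i^γ (1−y_i) log(1−ŷ_i)],
    L_DICE = −(2 Σ y_i ŷ_i) / (Σ y_i² + Σ ŷ_i²),

with γ = 2 by default. The encoder is a stack of SE-gated ResNeXt-style
bottleneck blocks; the decoder mirrors it with skip concatenation and
concurrent spatial+channel squeeze-and-excitation (scSE) gates; a
hypercolumn head fuses all decoder stages into one sigmoid probability map.
Full images are processed as 50 %-overlapping tiles, merged by mean,
color-filled (intensity = 255 · ŷ), and seam-smoothed by a dilated
split-transform-merge operator applied only along tile boundaries. Painted
channels are scored against ground truth with Dice and Recall (under a
2-gray-level tolerance matching rule), SSIM, and [0,1]-rescaled MSE, with
paired Wilcoxon signed-rank statistics; a phenotyping module recovers the
crypt/villus area ratio and LGR5+/UEA-I+ cell proportions from the
(virtual or real) channels.

Everything is exercisable without real data: a seeded generator simulates
paired phase/fluorescence organoid scenes with full ground truth (crypt
geometry and per-cell types). The network runs on a small NumPy autodiff
backbone (`phasepaint.nn`) — no GPU or deep-learning framework required.

## Worked example

Simulate one field and phenotype its fluorescent channels:

```python
from phasepaint import synthetic_organoid as so, phenotyping as ph

rec = so.make_dataset(1, seed=5)[0]          # phase + 3 channels + ground truth
rep = ph.phenotype_image({c: rec.targets[c] for c in ("nuclei", "lgr5", "ueai")})
true = rec.scene.crypt_mask.pixels
print(f"crypt/villus area ratio: {rep.crypt_villus_ratio:.3f} "
      f"(geometric truth {true.sum()/(true.size-true.sum()):.3f})")
print(f"cells: {rep.n_cells_total} total, {rep.n_cells_crypt} in crypts")
print(f"LGR5+ stem fraction of crypt cells: {rep.lgr5_fraction:.3f} "
      f"(generating parameter 0.400)")
print(f"UEA-I+ fraction of all cells: {rep.ueai_fraction:.3f}")
```

prints

```
crypt/villus area ratio: 0.064 (geometric truth 0.079)
cells: 587 total, 168 in crypts
LGR5+ stem fraction of crypt cells: 0.440 (generating parameter 0.400)
UEA-I+ fraction of all cells: 0.095
```

i.e. the density-based crypt segmentation recovers the geometric area ratio
to within ~19 % on this field and the counted stem-cell fraction lands 0.04
from the generating parameter.

The same pipeline is available from the shell:

```bash
phasepaint simulate --n 4 --seed 1 --out data/
phasepaint preprocess --images data/ --channel nuclei --tile-size 64 --out tiles/
phasepaint train --tiles tiles/ --checkpoint models/nuclei.npz --epochs 15
phasepaint paint --phase data/img000_phase.tif --checkpoint nuclei=models/nuclei.npz \
                 --tile-size 64 --out painted/
phasepaint evaluate --generated painted/ --truth data/ --channel nuclei --out scores/
phasepaint phenotype --images data/ --out phenotypes/
```

Each stage writes a provenance JSON (seed, config, versions) next to its
outputs.

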
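# atasm — adaptive texture-based active shape model for finger ultrasound

`atasm` segments the flexor tendon and the surrounding synovial sheath in
transverse finger ultrasound images (the A1-pulley scan plane used in
trigger-finger assessment), and classifies left/right hand pairs as
symptomatic or asymptomatic from texture features of the segmented tendon.
Everything runs self-contained: a seeded phantom generator renders synthetic
scans with known ground truth, so training, segmentation, evaluation and
classification are all exercised without clinical data.

It is written for image-analysis researchers and for anyone reproducing or
extending texture-augmented active shape models on musculoskeletal
ultrasound.

## The model

**Shape.** Tendon and sheath outlines are 20-point contours (4 extremal
anchors + 4 arc-equidistant points per arc). Training contours are aligned
by generalized Procrustes analysis and decomposed by PCA into a point
distribution model

    X = X̄ + P b,      −3√λᵢ ≤ bᵢ ≤ 3√λᵢ,

where `X̄` is the mean shape, the columns of `P` are shape modes and `λᵢ`
their variances.

**Energy.** A candidate contour is scored by a weighted sum over five terms
per control point `i`:

    F = Σₖ Σᵢ wᵢᵏ Fᵢᵏ

with `k` ∈ {curvature, area gradient (3×3 windows at ±2 px on the normal),
line gradient (5×1 masks), Gabor texture, Laws E5L5 texture}. The texture
terms are negative squared differences between trained 100-element texture
profiles (20 points × 5 samples every 2 px along the normal) and the
profiles sampled on the candidate contour. The gradient terms are signed
bright-inside/dark-outside for the tendon and flipped for the sheath.

**Adaptive weights.** Each weight is learned from training images by sliding
the control point along a ±10 px search line through the true boundary:
`wᵢᵏ = meanₜ(σ·F/F̃)` with `F` the term value at the truth, `F̃` the line
maximum and `σ` the line spread — large exactly where the term is
informative.

**Optimization.** The tendon is localized coarse-to-fine (half-resolution
sliding-block SAD against a trained mean intensity template, then Powell
refinement of a similarity transform). The shape is then fitted by
alternating Powell pose refinement with a genetic algorithm over `b`
(population 50, roulette selection, single-point crossover 0.5, mutation
0.01, elitism, 10-generation convergence patience). The sheath model is
initialized at the tendon centroid, optimized the same way, and
post-processed: its lower boundary is replaced by the lower tendon arc
(within ±30° of the downward vertical) and the side gaps are bridged by
tangent-continuous parabolas.

**Classification.** From each hand, a 41×21 px patch at the tendon centre
yields SWT/wavelet-packet subband statistics (haar, db4, db6, coif1), 12
Haralick GLCM features in 4 directions, and the tendon/sheath areas.
Left−right feature differences are ranked by the divergence value

    D(f) = (σₙ−σₐ)² (1+σₙ+σₐ)² / (σₙσₐ)

and the top 20 feed an RBF SVM. Agreement metrics are the mean absolute
contour distance (MAD, px) and the Dice similarity coefficient (DSC).

## Worked example

```python
import numpy as np
from atasm import (AtasmSegmenter, PhantomSpec, generate_phantom,
                   generate_training_set, segment_tendon, segment_sheath,
                   mad, dsc)

train = generate_training_set(20, seed=42)
images  = [t[0] for t in train]
tendons = [t[1]["tendon"] for t in train]
sheaths = [t[1]["sheath"] for t in train]

tendon_seg = AtasmSegmenter(target="tendon", random_state=0).fit(images, tendons)
sheath_seg = AtasmSegmenter(target="sheath", random_state=0).fit(images, sheaths)

image, truth, group = generate_phantom(PhantomSpec(rng_seed=777))
res  = segment_tendon(image, tendon_seg, seed=1)
res2 = segment_sheath(image, res, sheath_seg, seed=1)

print("group:", res.group.label)
print("tendon MAD %.2f px, DSC %.3f" % (mad(res.tendon, truth["tendon"]),
                                        dsc(res.tendon, truth["tendon"])))
print("sheath MAD %.2f px" % mad(res2.sheath, truth["sheath"]))
```

prints

```
group: clear
tendon MAD 0.59 px, DSC 0.984
sheath MAD 1.07 px
```

i.e. on a speckled phantom with a clear bottom boundary, the fitted tendon
contour deviates from the known truth by under one pixel on average and
overlaps it with Dice 0.984; the sheath boundary is within about one pixel.

The same workflow is available from the shell:

```bash
atasm simulate --kind training --n 20 --seed 42 --out data/
atasm train --images data/ --contours data/ --out tendon.npz
atasm segment --image data/phantom_000.png --model tendon.npz --out out/
atasm evaluate --pred out/ --truth data/ --out report.csv
```

## Layout

- `src/atasm/contour.py`, `shape_model.py` — contours, Procrustes + PCA model
- `src/atasm/texture.py`, `energy.py` — texture images/profiles, energy terms, adaptive weights
- `src/atasm/optimize.py`, `localization.py` — GA, Powell, template matching
- `src/atasm/pipeline.py` — `AtasmSegmenter`, sheath post-processing, grouping
- `src/atasm/classification.py` — features, divergence selection, SVM
- `src/atasm/phantom.py` — synthetic phantom and cohort generators
- `src/atasm/metrics.py`, `io.py`, `cli.py` — MAD/DSC/rates, files, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
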
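# meningiodet

Detection and delineation of meningioma on 2-D brain MRI slices, built
around four components:

1. **Finite ridgelet transform** — the finite Radon transform (FRAT) of a
   prime-side image sums pixels over the p+1 families of mod-p lines
   `{(i, j) : j = k·i + l (mod p)}` plus the constant-row family; a 1-D
   orthonormal wavelet (Haar by default) along each projection's offset axis
   yields direction-selective coefficients R(i, j).
2. **Pixel-intensity features** of the coefficient grid (C1 × C2, 1-based
   indices):

       PIF = Σ R²        / (C1²C2²)        PMF = Σ R   / (C1C2)
       PVF = Σ(R−i)² + Σ(R−j)² / (C1C2)    FIF = Σ R·i·j / ((C1+1)(C2+1))
       SIF = Σ R·i²j²    / ((C1+1)²(C2+1)²)

   evaluated both globally and on sliding blocks of the grid (a 5-channel
   feature map).
3. **Hybrid CNN classifier** — two convolution + pooling stages over the
   feature maps, a linear embedding, and a two-cluster **spatial fuzzy
   c-means (SFCM)** output layer in place of a softmax: a slice is labelled
   meningioma / non-meningioma by fuzzy membership against frozen cluster
   centroids.
4. **Probability-based morphological segmentation** — grayscale opening and
   closing of the slice, per-pixel intensity-probability maps of both,
   division of each morphological image by the averaged probability map, and
   the absolute difference `M_diff = |M_o/A_t − M_c/A_t|`, in which compact
   low-intensity tumors light up because their intensities are globally rare
   and locally textured. A mixture-model threshold with hole filling and
   small-component removal turns the response into a binary mask.

Everything is validated on a seeded **phantom generator** (bright skull
annulus, textured parenchyma, dark tumor disk with exact ground-truth mask),
so the full pipeline runs and is scored without any clinical dataset. See
`docs/methods.md` for the model details, design decisions and limitations.

## Worked example

```python
from meningiodet import (PhantomSpec, StructuringElement, generate_phantom,
                         segment, confusion_counts, compute_metrics)

phantom = generate_phantom(PhantomSpec(seed=5), with_tumor=True)
mask = segment(phantom.image, StructuringElement(radius=3), min_area=30)
report = compute_metrics(confusion_counts(mask, phantom.mask))
print(mask.area, round(report.dice, 3))
```

Running `python examples/segment_phantom.py` (the same computation with
commentary) prints:

```
planted tumor: 1018 px, mean intensity 75.0 vs parenchyma ~120
recovered mask: 1170 px
Dice overlap with ground truth: 0.907
pixel-level sensitivity 97.4%, specificity 98.8%
```

i.e. the segmenter recovers the planted 1018-pixel tumor with 90.7% Dice
overlap, missing 2.6% of tumor pixels and mislabelling 1.2% of background.
The other example scripts cover the ridgelet/feature stage
(`examples/ridgelet_features.py`), training and held-out classification
(`examples/train_classify.py`), and the two metric-reporting conventions
(`examples/metric_conventions.py`).

## Command line

```bash
meningiodet phantom --n-per-class 30 --seed 42 --out-dir data/
meningiodet train --manifest data/manifest.csv --seed 42 \
    --conv1-filters 16 --conv2-filters 32 --out-dir run/
meningiodet classify --image data/meningioma_0007.png --model run/model.zip
meningiodet segment --image data/meningioma_0007.png --out mask.png --overlay overlay.png
meningiodet evaluate --manifest data/manifest.csv --model run/model.zip --out-dir eval/
meningiodet ablate --manifest data/manifest.csv --seed 42 --out-dir ablation/
```

`evaluate` writes a per-image metrics CSV with an `Average` row;
`ablate` trains once per feature subset (full set plus each single
feature).

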
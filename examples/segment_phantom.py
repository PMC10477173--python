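"""Segment the tumor in a synthetic slice with the probability-based
morphological pipeline and score it against the known ground truth.

The pipeline opens and closes the slice with a flat disk, converts both
results to per-pixel intensity-probability maps, divides the morphological
images by the averaged probability map and takes the absolute difference:
pixels whose intensities are globally rare AND locally textured — the tumor —
light up. Dice close to 1 means the recovered mask matches the planted disk.
"""

import numpy as np

from meningiodet import (
    PhantomSpec,
    StructuringElement,
    compute_metrics,
    confusion_counts,
    generate_phantom,
    segment,
)

phantom = generate_phantom(PhantomSpec(seed=5), with_tumor=True)
true_area = phantom.mask.area
print(f"planted tumor: {true_area} px, mean intensity "
      f"{phantom.image.pixels[phantom.mask.mask].mean():.1f} vs parenchyma ~120")

mask = segment(phantom.image, StructuringElement(radius=3), min_area=30)
report = compute_metrics(confusion_counts(mask, phantom.mask))

print(f"recovered mask: {mask.area} px")
print(f"Dice overlap with ground truth: {report.dice:.3f}")
print(f"pixel-level sensitivity {report.sensitivity:.1f}%, "
      f"specificity {report.specificity:.1f}%")
print("Dice = 2*TP / (2*TP + FP + FN); 1.0 would be a pixel-perfect mask.")
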
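"""Train the hybrid CNN + SFCM classifier on a small phantom dataset and
report held-out accuracy.

Filter counts are reduced from the full-scale 512/1024 architecture to 16/32
so the example runs in well under a minute on one CPU; the pipeline
(ridgelet -> feature maps -> conv/pool stack -> fuzzy c-means output layer)
is the full one.
"""

import tempfile

import numpy as np

from meningiodet import (
    HCNNConfig,
    PhantomSpec,
    classify,
    generate_dataset,
    load_image,
    train,
)

with tempfile.TemporaryDirectory() as workdir:
    manifest = generate_dataset(30, PhantomSpec(seed=42), workdir)
    print(f"dataset: {len(manifest)} slices, half train / half test")

    config = HCNNConfig(conv1_filters=16, conv2_filters=32, seed=42)
    model = train(manifest, config)
    print(f"supervised stage: {len(model.training_loss)} epochs, "
          f"final loss {model.training_loss[-1]:.4f}")
    print(f"SFCM output layer converged in {model.sfcm.n_iter} iterations; "
          f"cluster map {model.sfcm.cluster_to_label}")

    for split in ("train", "test"):
        records = manifest.subset(split).records
        hits = sum(
            classify(load_image(r.image_path), model).label == r.label
            for r in records
        )
        print(f"{split} accuracy: {hits}/{len(records)} = {hits/len(records):.2f}")
print("accuracy is the fraction of slices whose meningioma / non-meningioma "
      "call matches the generator's label")
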
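"""Patch classification on a synthetic vessel phantom.

Generates a phantom image of bright curvilinear tubes, samples labeled
pixels from the ground-truth mask, extracts raw patches plus Gabor
responses, and trains a semi-supervised forest with only 20 labels —
the pipeline a retinal-vessel segmentation run would use, at desk
scale.
"""

import numpy as np

from gerforest import (
    ForestConfig,
    PartiallyLabeledDataset,
    PatchSpec,
    extract_patches,
    gabor_features,
    sample_pixels,
    synthetic,
    train_forest,
)
from gerforest.datasets import split_labeled_subset

image, mask = synthetic.make_vessel_image(height=160, width=160, n_tubes=4, snr=8.0, seed=0)
points, labels = sample_pixels(mask, n_pos=300, n_neg=300, seed=0)

patches = extract_patches(image, points, PatchSpec(7, 7, 1))
gabor = gabor_features(image, points, wavelengths=(2.0, 4.0, 8.0), n_orientations=4)
X = np.hstack([patches, gabor])
print(f"feature table: {X.shape[0]} pixels x {X.shape[1]} features "
      f"({patches.shape[1]} patch + {gabor.shape[1]} Gabor)")

full = PartiallyLabeledDataset(
    X_labeled=X[:400], y_labeled=labels[:400],
    X_unlabeled=np.empty((0, X.shape[1])), n_classes=2,
)
train = split_labeled_subset(full, n=20, seed=0)
forest = train_forest(train, ForestConfig(n_trees=25, seed=0), variant="graph")

X_test, y_test = X[400:], labels[400:]
acc = np.mean(forest.predict(X_test) == y_test)
print(f"held-out pixel accuracy with 20 labels + 380 unlabeled: {acc:.1%}")
print("-> vessel vs background, graph-embedded forest on patch+Gabor features")
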
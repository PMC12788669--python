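"""Train the dual-branch classifier on a separable phantom task.

Two widely separated severity grades (1 vs 5) on 64 px slices make an
easily learnable benchmark: the fused image-CNN + mask-DNN model reaches
~0.9 held-out accuracy at n=300 within ~1 minute on one CPU (1.0 at the
n=500 scale the acceptance script uses).
"""

import numpy as np

from dbmca.models import (TrainConfig, build_dbmca, predict,
                          small_cnn_branch, small_dnn_branch, train_model)
from dbmca.phantom import generate_phantom, separable_config

dataset = generate_phantom(separable_config(300, seed=1))
images, masks, labels = dataset.image_array(), dataset.mask_array(), dataset.label_array()

rng = np.random.default_rng(0)
perm = rng.permutation(len(labels))
train_idx, test_idx = perm[:240], perm[240:]

spec = build_dbmca(small_cnn_branch(), small_dnn_branch())
print(f"fused feature width: {spec.fused_width} "
      f"(= {spec.image_branch.output_width} image + {spec.mask_branch.output_width} mask)")

model = train_model(spec, (images[train_idx], masks[train_idx]), labels[train_idx],
                    TrainConfig(max_epochs=25, early_stopping_patience=4, seed=3))
print(f"stopped at epoch {model.stopped_epoch}, restored epoch {model.best_epoch}")

y_pred, probs = predict(model, (images[test_idx], masks[test_idx]))
acc = (y_pred == labels[test_idx]).mean()
print(f"held-out accuracy: {acc:.3f} on {len(test_idx)} slices")
print(f"class probabilities sum to 1: {np.allclose(probs.sum(axis=1), 1.0)}")
# accuracy ~0.9: grades 1 and 5 differ by a factor ~3 in nodule diameter,
# which both branches can read
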
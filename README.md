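# dbmca

Dual-branch lung-nodule severity classification on CT slices, with a fully
synthetic validation path.

Computer-aided grading of lung nodules from chest CT usually has two views
of the same lesion: the grayscale slice itself, and a binary segmentation
mask marking the nodule pixels. The two are complementary — the image
carries texture and context, the mask carries clean shape and size — and
this package implements a classifier that fuses them: a convolutional
branch over the full image and a dense branch over the flattened mask,
joined by plain feature concatenation and a softmax over six severity
classes (0 = non-cancerous, 1–5 = increasing malignancy grade).

The model is trained and evaluated as

  p(class | image, mask) = softmax(W · [f_cnn(image) ‖ f_dnn(mask)])

where `f_cnn` is a four-stage CNN (conv → ReLU → maxpool → dropout, ×4,
then dense layers), `f_dnn` is a dense network on the raw flattened mask,
and `‖` is concatenation with no fusion weights. Baselines for comparison:
each branch alone on either modality, and a linear SVM on raw flattened
pixels (L2-regularized squared-hinge, C = 4, tol = 10⁻³, one-vs-rest, no
scaling). Model differences are judged with fold-paired t-tests
(t = d̄·√n / s_d, n−1 df) and one-way ANOVA.

Everything upstream of the classifier is included: Gabor/denoise
preprocessing, marker-controlled watershed segmentation with the clinical
≥ 3 mm size gate, region centering, and the five-feature nodule
morphometry (centroid, equivalent diameter, perimeter, mean intensity,
eccentricity). Because the real archives this pipeline targets are large
and external, the package ships a **synthetic CT phantom generator** whose
slices, sparse masks (85–95% background) and severity labels have the
statistical structure the pipeline assumes — every stage is testable on a
laptop with no downloads. See `docs/methods.md` for the full model and
phantom description.

## Worked example

```python
import numpy as np
from dbmca.models import (TrainConfig, build_dbmca, predict,
                          small_cnn_branch, small_dnn_branch, train_model)
from dbmca.phantom import generate_phantom, separable_config

dataset = generate_phantom(separable_config(300, seed=1))
images, masks, labels = (dataset.image_array(), dataset.mask_array(),
                         dataset.label_array())
perm = np.random.default_rng(0).permutation(300)
tr, te = perm[:240], perm[240:]

spec = build_dbmca(small_cnn_branch(), small_dnn_branch())
model = train_model(spec, (images[tr], masks[tr]), labels[tr],
                    TrainConfig(max_epochs=25, early_stopping_patience=4, seed=3))
y, probs = predict(model, (images[te], masks[te]))
print((y == labels[te]).mean())
```

This prints `0.9166666666666666`: the task is two widely separated
severity grades (nodule burdens differing ~3× in diameter), and the fused
model learns it in under a minute from 240 training slices — at n = 500
(the size the acceptance script uses) it reaches 1.0 held-out accuracy.
`probs` rows are softmax distributions over the six classes. The `examples/` directory has one short script per
capability — phantom generation, segmentation + morphometry, dual-branch
training, paired-t comparison, and the end-to-end experiment — each
printing the numbers it computes and what they mean.

A thin CLI mirrors the pipeline stages:

```bash
dbmca phantom --n 100 --seed 1 --out data/
dbmca segment --in data/ --out seg/ --min-diameter-mm 3.0
dbmca run --n 60 --k 3 --seed 5 --out report/
```

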
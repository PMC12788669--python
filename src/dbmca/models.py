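"""The dual-branch classifier and its baselines.

The dual-branch model (DbMCA) joins two sub-networks by plain feature
concatenation — no fusion weights — and classifies the fused vector with a
softmax head over six severity classes (0 = non-cancerous, 1-5 = malignancy
grades):

* the image branch is a CNN in the four-stage / 19-step pattern:
  4 x [conv -> ReLU -> maxpool -> dropout], then flatten and two dense(ReLU)
  steps ending in the branch feature layer;
* the mask branch is a single-stage / 7-step dense network:
  flatten -> dense(ReLU) -> dropout -> dense(ReLU) -> dropout -> dense ->
  ReLU.  (At full scale the hidden width is 512 units.)

Baselines: each branch trained alone with a linear softmax head on either
modality, and a linear SVM on raw flattened pixels configured like LIBLINEAR
``-s 2 -c 4 -e 0.001`` (L2-regularized L2-loss SVC, primal, one-vs-rest,
C = 4, tol = 1e-3, no feature scaling).

Training uses Adam on softmax cross-entropy with a 10% validation holdout
and early stopping (best-validation parameters restored).  Argmax ties break
to the lowest class index.  Dropout is off at prediction time, so repeated
prediction is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn

N_CLASSES = 6

# layer descriptors: ("conv", filters) | ("relu",) | ("maxpool",)
# | ("dropout", rate) | ("flatten",) | ("dense", units[, "relu"])
LayerDesc = tuple


@dataclass(frozen=True)
class BranchSpec:
    kind: str  # "cnn" | "dnn"
    layers: tuple[LayerDesc, ...]
    output_width: int

    def __post_init__(self) -> None:
        if self.kind not in ("cnn", "dnn"):
            raise ValueError(f"unknown branch kind {self.kind!r}")
        if self.output_width <= 0:
            raise ValueError("output_width must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Dual-branch fusion model.

    ``modality_dropout`` is the per-sample probability of zeroing the entire
    mask-branch feature vector during training (inverted scaling).  Jointly
    trained concatenation fusion otherwise collapses onto the fast-memorizing
    dense mask branch, starving the convolutional image branch of gradient;
    stochastically ablating the shortcut-prone branch forces the head to
    keep an image-only classification pathway while mask features stay
    auxiliary.  It is inactive at prediction time.
    """

    image_branch: BranchSpec
    mask_branch: BranchSpec
    fused_width: int
    n_classes: int = N_CLASSES
    head_hidden: int = 32
    modality_dropout: float = 0.25

    def __post_init__(self) -> None:
        expected = self.image_branch.output_width + self.mask_branch.output_width
        if self.fused_width != expected:
            raise ValueError(
                f"fused_width {self.fused_width} != sum of branch widths {expected}"
            )


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 45  # the full-scale regimen runs past 40 epochs
    steps_per_epoch: int | None = None  # None = one full pass (~600 at full scale)
    early_stopping_patience: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class SvmConfig:
    """LIBLINEAR-style linear SVC: ``-s 2 -c 4 -e 0.001``."""

    C: float = 4.0
    tolerance: float = 1e-3
    multiclass: str = "ovr"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.tolerance <= 0:
            raise ValueError("C and tolerance must be positive")


@dataclass
class TrainedModel:
    spec: object
    network: object  # _DualNet | _SingleNet | fitted LinearSVC
    history: list[dict] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def default_cnn_branch(
    output_width: int = 32,
    filters: Sequence[int] = (8, 16, 32, 32),
    dense_units: int = 64,
    dropout: float = 0.25,
) -> BranchSpec:
    """Four-stage / 19-step CNN branch."""
    layers: list[LayerDesc] = []
    for f in filters:
        layers += [("conv", f), ("relu",), ("maxpool",), ("dropout", dropout)]
    layers += [("flatten",), ("dense", dense_units, "relu"), ("dense", output_width, "relu")]
    assert len(layers) == 19
    return BranchSpec(kind="cnn", layers=tuple(layers), output_width=output_width)


def default_dnn_branch(
    output_width: int = 32, hidden: int = 512, dropout: float = 0.5
) -> BranchSpec:
    """Single-stage / 7-step dense branch."""
    layers: tuple[LayerDesc, ...] = (
        ("flatten",),
        ("dense", hidden, "relu"),
        ("dropout", dropout),
        ("dense", hidden, "relu"),
        ("dropout", dropout),
        ("dense", output_width),
        ("relu",),
    )
    assert len(layers) == 7
    return BranchSpec(kind="dnn", layers=layers, output_width=output_width)


def small_cnn_branch(output_width: int = 24) -> BranchSpec:
    """Desk-scale CNN branch for 64 px inputs."""
    return default_cnn_branch(output_width=output_width, filters=(6, 12, 24, 24), dense_units=48)


def small_dnn_branch(output_width: int = 24) -> BranchSpec:
    """Desk-scale dense branch for 64 px inputs."""
    return default_dnn_branch(output_width=output_width, hidden=96)


def build_dbmca(
    image_cfg: BranchSpec | None = None,
    mask_cfg: BranchSpec | None = None,
    n_classes: int = N_CLASSES,
) -> ModelSpec:
    """Declarative dual-branch model: concatenation fusion, softmax head."""
    image_cfg = image_cfg or default_cnn_branch()
    mask_cfg = mask_cfg or default_dnn_branch()
    return ModelSpec(
        image_branch=image_cfg,
        mask_branch=mask_cfg,
        fused_width=image_cfg.output_width + mask_cfg.output_width,
        n_classes=n_classes,
    )


def flatten_input(grid: np.ndarray) -> np.ndarray:
    """Row-major flattening of a 2D grid to a vector of length H*W."""
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError(f"flatten_input expects a 2D grid, got shape {grid.shape}")
    return grid.reshape(-1)


# --------------------------------------------------------------------------
# network realization


def _realize_branch(
    spec: BranchSpec, input_shape: tuple[int, int], rng: np.random.Generator
) -> tuple[nn.Sequential, int]:
    """Instantiate a branch for (H, W) single-channel input; returns the net
    and its output width."""
    h, w = input_shape
    layers: list[nn.Layer] = []
    if spec.kind == "cnn":
        c = 1
        for desc in spec.layers:
            op = desc[0]
            if op == "conv":
                layers.append(nn.Conv2D(c, desc[1], rng))
                c = desc[1]
            elif op == "relu":
                layers.append(nn.ReLU())
            elif op == "maxpool":
                layers.append(nn.MaxPool2())
                h, w = h // 2, w // 2
            elif op == "dropout":
                layers.append(nn.Dropout(desc[1]))
            elif op == "flatten":
                layers.append(nn.Flatten())
                c, width = None, c * h * w
            elif op == "dense":
                layers.append(nn.Dense(width, desc[1], rng))
                width = desc[1]
                if len(desc) > 2 and desc[2] == "relu":
                    layers.append(nn.ReLU())
            else:
                raise ValueError(f"unknown layer descriptor {desc!r}")
    else:  # dnn
        width = h * w
        for desc in spec.layers:
            op = desc[0]
            if op == "flatten":
                layers.append(nn.Flatten())
            elif op == "dense":
                layers.append(nn.Dense(width, desc[1], rng))
                width = desc[1]
                if len(desc) > 2 and desc[2] == "relu":
                    layers.append(nn.ReLU())
            elif op == "relu":
                layers.append(nn.ReLU())
            elif op == "dropout":
                layers.append(nn.Dropout(desc[1]))
            else:
                raise ValueError(f"unknown layer descriptor {desc!r}")
    if width != spec.output_width:
        raise ValueError(
            f"branch realizes width {width}, spec declares {spec.output_width}"
        )
    return nn.Sequential(layers), width


class _DualNet:
    """Instantiated dual-branch network: two branches, concat, dense head."""

    def __init__(self, spec: ModelSpec, input_shape: tuple[int, int], rng: np.random.Generator):
        self.spec = spec
        self.image_net, wi = _realize_branch(spec.image_branch, input_shape, rng)
        self.mask_net, wm = _realize_branch(spec.mask_branch, input_shape, rng)
        self._wi = wi
        self.head = nn.Sequential(
            [
                nn.Dense(spec.fused_width, spec.head_hidden, rng),
                nn.ReLU(),
                nn.Dense(spec.head_hidden, spec.n_classes, rng),
            ]
        )
        self._rng = rng

    def forward(self, images: np.ndarray, masks: np.ndarray, *, train: bool = False) -> np.ndarray:
        """Class probabilities for a batch of (image, mask) pairs."""
        fi = self.image_net.forward(images[:, None, :, :], train=train, rng=self._rng)
        fm = self.mask_net.forward(masks, train=train, rng=self._rng)
        p = self.spec.modality_dropout
        if train and p > 0.0:
            keep = 1.0 - p
            self._mod_keep = (
                (self._rng.random((len(fm), 1)) < keep) / keep
            ).astype(nn.DTYPE)
            fm = fm * self._mod_keep
        else:
            self._mod_keep = None
        fused = np.concatenate([fi, fm], axis=1)
        logits = self.head.forward(fused, train=train, rng=self._rng)
        return nn.softmax(logits)

    def backward(self, probs: np.ndarray, labels: np.ndarray) -> None:
        grad = self.head.backward(nn.softmax_ce_grad(probs, labels))
        gi, gm = grad[:, : self._wi], grad[:, self._wi :]
        if self._mod_keep is not None:
            gm = gm * self._mod_keep
        self.image_net.backward(gi)
        self.mask_net.backward(gm)

    def params(self):
        return self.image_net.params() + self.mask_net.params() + self.head.params()

    def grads(self):
        return self.image_net.grads() + self.mask_net.grads() + self.head.grads()


class _SingleNet:
    """One branch with a linear softmax classifier on its features."""

    def __init__(self, spec: BranchSpec, input_shape: tuple[int, int],
                 n_classes: int, rng: np.random.Generator):
        self.spec = spec
        self.net, width = _realize_branch(spec, input_shape, rng)
        self.classifier = nn.Dense(width, n_classes, rng)
        self.n_classes = n_classes
        self._rng = rng

    def forward(self, inputs: np.ndarray, *, train: bool = False) -> np.ndarray:
        x = inputs[:, None, :, :] if self.spec.kind == "cnn" else inputs
        feats = self.net.forward(x, train=train, rng=self._rng)
        logits = self.classifier.forward(feats, train=train, rng=self._rng)
        return nn.softmax(logits)

    def backward(self, probs: np.ndarray, labels: np.ndarray) -> None:
        grad = self.classifier.backward(nn.softmax_ce_grad(probs, labels))
        self.net.backward(grad)

    def params(self):
        return self.net.params() + self.classifier.params()

    def grads(self):
        return self.net.grads() + self.classifier.grads()


# --------------------------------------------------------------------------
# training


def early_stopping_trace(val_losses: Sequence[float], patience: int) -> tuple[int, int]:
    """Apply the patience rule to a validation-loss sequence.

    Returns (stopped_epoch, best_epoch), 1-based: training stops at the first
    epoch where the loss has failed to improve on the running best for
    ``patience`` consecutive epochs (or at the last epoch).
    """
    best, best_epoch, bad = np.inf, 0, 0
    stopped = len(val_losses)
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best, best_epoch, bad = loss, epoch, 0
        else:
            bad += 1
            if bad >= patience:
                stopped = epoch
                break
    return stopped, best_epoch


def _validate_labels(labels: np.ndarray, n_classes: int) -> None:
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("training data contains a single class")
    if present.min() < 0 or present.max() >= n_classes:
        raise ValueError(
            f"labels {present.tolist()} fall outside the {n_classes}-class range"
        )


def _stratified_holdout(
    labels: np.ndarray, frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(frac * len(idx))))
        val_idx.append(idx[:k])
        train_idx.append(idx[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train_model(
    spec: ModelSpec | BranchSpec,
    inputs: np.ndarray | tuple[np.ndarray, np.ndarray],
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> TrainedModel:
    """Fit a dual-branch model (inputs = (images, masks)) or a single branch
    (inputs = one (n, H, W) array) with Adam, early stopping on a stratified
    10% validation holdout, and best-validation restore.  Deterministic for a
    fixed ``cfg.seed``."""
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)

    if isinstance(spec, ModelSpec):
        images, masks = (np.asarray(a, dtype=nn.DTYPE) for a in inputs)
        if images.shape != masks.shape:
            raise ValueError("image and mask stacks must be shape-consistent")
        n, h, w = images.shape
        _validate_labels(labels, spec.n_classes)
        net = _DualNet(spec, (h, w), rng)
        batches = lambda idx: (images[idx], masks[idx])
        fwd = lambda data, train: net.forward(*data, train=train)
    else:
        arr = np.asarray(inputs, dtype=nn.DTYPE)
        n, h, w = arr.shape
        _validate_labels(labels, N_CLASSES)
        net = _SingleNet(spec, (h, w), N_CLASSES, rng)
        batches = lambda idx: (arr[idx],)
        fwd = lambda data, train: net.forward(*data, train=train)
    if len(labels) != n:
        raise ValueError("labels length must match the number of samples")

    tr_idx, val_idx = _stratified_holdout(labels, cfg.val_fraction, rng)
    val_data, val_y = batches(val_idx), labels[val_idx]
    opt = nn.Adam(net.params(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    history: list[dict] = []
    best_loss, best_epoch, bad = np.inf, 0, 0
    best_params = nn.snapshot_params(net.params())
    stopped = cfg.max_epochs

    for epoch in range(1, cfg.max_epochs + 1):
        perm = tr_idx[rng.permutation(len(tr_idx))]
        losses = []
        n_steps = 0
        for start in range(0, len(perm), cfg.batch_size):
            if cfg.steps_per_epoch is not None and n_steps >= cfg.steps_per_epoch:
                break
            idx = perm[start : start + cfg.batch_size]
            probs = fwd(batches(idx), True)
            losses.append(nn.cross_entropy(probs, labels[idx]))
            net.backward(probs, labels[idx])
            opt.step(net.grads())
            n_steps += 1
        val_probs = fwd(val_data, False)
        val_loss = nn.cross_entropy(val_probs, val_y)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss, best_epoch, bad = val_loss, epoch, 0
            best_params = nn.snapshot_params(net.params())
        else:
            bad += 1
            if bad >= cfg.early_stopping_patience:
                stopped = epoch
                break

    nn.restore_params(net.params(), best_params)
    return TrainedModel(spec=spec, network=net, history=history,
                        stopped_epoch=stopped, best_epoch=best_epoch)


def train_svm(vectors: np.ndarray, labels: np.ndarray, cfg: SvmConfig | None = None) -> TrainedModel:
    """Fit the linear SVM baseline on raw flattened vectors (no scaling)."""
    from sklearn.svm import LinearSVC

    cfg = cfg or SvmConfig()
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2:
        raise ValueError("train_svm expects a 2D (n_samples, width) array")
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) != len(vectors):
        raise ValueError("labels length must match the number of vectors")
    # LIBLINEAR -s 2: L2-reg L2-loss SVC solved in the primal, one binary
    # problem per class (one-vs-rest)
    est = LinearSVC(C=cfg.C, tol=cfg.tolerance, loss="squared_hinge", dual=False)
    est.fit(vectors, labels)
    est._train_width = vectors.shape[1]
    return TrainedModel(spec=cfg, network=est)


def predict(
    model: TrainedModel, inputs
) -> tuple[np.ndarray, np.ndarray | None]:
    """Predicted labels (and class probabilities; None for the SVM).

    Labels are the argmax of probabilities/decision scores; ties break to
    the lowest class index.  Dropout is inactive, so repeated calls agree.
    """
    net = model.network
    if isinstance(net, _DualNet):
        images, masks = (np.asarray(a, dtype=nn.DTYPE) for a in inputs)
        probs = net.forward(images, masks, train=False)
        return probs.argmax(axis=1), probs
    if isinstance(net, _SingleNet):
        probs = net.forward(np.asarray(inputs, dtype=nn.DTYPE), train=False)
        return probs.argmax(axis=1), probs
    # sklearn LinearSVC
    vectors = np.asarray(inputs, dtype=np.float64)
    if not hasattr(net, "coef_"):
        raise ValueError("model is not fitted")
    if vectors.shape[1] != net._train_width:
        raise ValueError(
            f"input width {vectors.shape[1]} != training width {net._train_width}"
        )
    scores = net.decision_function(vectors)
    if scores.ndim == 1:  # binary: positive score = classes_[1]
        labels = net.classes_[(scores > 0).astype(int)]
    else:
        labels = net.classes_[scores.argmax(axis=1)]
    return np.asarray(labels), None
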
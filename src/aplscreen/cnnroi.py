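"""Per-view CNN training, Grad-CAM heatmaps and ROI extraction.

One binary CNN is trained per scattergram view (DIFF/WNB x SS-FL/FS-FL) to
discriminate APL from non-APL samples.  Grad-CAM then localizes the image
regions driving the APL logit: channel weights are the spatial means of the
logit's gradient on the last convolutional feature maps, the weighted map
is rectified, bilinearly upsampled to image size and max-normalized.
Thresholding the heatmap and keeping large connected components yields the
ROI masks that the quantification stage intersects with particle pixels.

Two architectures are provided: the classic 13-conv/3-FC VGG16 layout with
a 2-way head (the full-scale configuration) and ``vgg-tiny``, a three-block
reduction used for desk-scale cohorts where VGG16 would be badly
over-parameterized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.transform import resize as _sk_resize

from . import nn
from .prep import RESOLUTION, ScattergramImage, ViewTag
from .synthgram import ConfigurationError, ValidationError

#: channel widths per conv block; "M" is 2x2 max pooling
ARCH_CONFIGS: dict[str, list] = {
    "vgg16": [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M"],
    "vgg-tiny": [8, "M", 16, "M", 32, "M"],
}
#: fully connected widths after the conv stack (final layer is the 2-way head)
FC_CONFIGS: dict[str, list[int]] = {"vgg16": [4096, 4096, 2], "vgg-tiny": [2]}


@dataclass
class TrainHyperparams:
    """SGD settings; the defaults are the full-scale training configuration
    (cross-entropy loss, momentum SGD)."""

    learning_rate: float = 1e-6
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")


@dataclass
class CnnModel:
    """A per-view classifier: Sequential net + Grad-CAM hook bookkeeping.

    ``hook_index`` is the index of the layer whose *output* is the Grad-CAM
    feature map: the rectified activation of the last convolutional layer.
    """

    arch: str
    net: nn.Sequential
    hook_index: int
    seed: int
    input_size: int = RESOLUTION
    view_name: str = ""

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def logits(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        x = _to_input(images, self.input_size)
        out = [self.net.forward(x[i:i + batch_size])
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(images).astype(np.float64))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.logits(images).argmax(axis=1)


@dataclass
class Heatmap:
    """Max-normalized Grad-CAM map in [0, 1] for the APL class."""

    values: np.ndarray
    view: ViewTag | None = None
    target_class: int = 1


@dataclass
class ROISet:
    """Disjoint binary components of a thresholded heatmap, area-sorted."""

    masks: list[np.ndarray] = field(default_factory=list)
    threshold: float = 0.5
    min_area: int = 20

    def union(self, shape=(RESOLUTION, RESOLUTION)) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for m in self.masks:
            out |= m
        return out

    def __len__(self) -> int:
        return len(self.masks)


def count_arch_params(arch: str, input_size: int = RESOLUTION) -> int:
    """Analytic parameter count for an architecture (no allocation)."""
    if arch not in ARCH_CONFIGS:
        raise ConfigurationError(f"unknown architecture {arch!r}")
    total = 0
    in_ch, size = 3, input_size
    for item in ARCH_CONFIGS[arch]:
        if item == "M":
            size //= 2
        else:
            total += item * in_ch * 9 + item
            in_ch = item
    width = in_ch * size * size
    for out in FC_CONFIGS[arch]:
        total += width * out + out
        width = out
    return total


def build_cnn(arch: str, seed: int = 0, input_size: int = RESOLUTION,
              dtype=np.float32, view_name: str = "") -> CnnModel:
    """Construct a seeded, deterministically initialized per-view CNN."""
    if arch not in ARCH_CONFIGS:
        raise ConfigurationError(f"unknown architecture {arch!r}")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch, size = 3, input_size
    hook_index = -1
    for item in ARCH_CONFIGS[arch]:
        if item == "M":
            layers.append(nn.MaxPool2d())
            size //= 2
        else:
            layers.append(nn.Conv2d(in_ch, item, rng=rng, dtype=dtype))
            layers.append(nn.ReLU())
            hook_index = len(layers) - 1  # activation of the most recent conv
            in_ch = item
    layers.append(nn.Flatten())
    width = in_ch * size * size
    fcs = FC_CONFIGS[arch]
    for i, out in enumerate(fcs):
        layers.append(nn.Linear(width, out, rng=rng, dtype=dtype))
        if i < len(fcs) - 1:
            layers.append(nn.ReLU())
        width = out
    model = CnnModel(arch, nn.Sequential(layers), hook_index, seed, input_size,
                     view_name)
    assert model.n_params == count_arch_params(arch, input_size)
    return model


def _to_input(images: np.ndarray, input_size: int) -> np.ndarray:
    """(N, H, W, 3) uint8 in [0, 255] -> float32 in [0, 1] (NHWC)."""
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != (input_size, input_size, 3):
        raise ValidationError(f"expected (N, {input_size}, {input_size}, 3) images")
    return np.ascontiguousarray(x.astype(np.float32) / 255.0)


def train_cnn(model: CnnModel, images: np.ndarray, labels: np.ndarray,
              hp: TrainHyperparams) -> list[dict]:
    """Train in place; returns a per-epoch history of mean minibatch loss
    and training accuracy.  Deterministic given (model seed, hp.seed)."""
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise ValidationError("training labels must contain both classes")
    x = _to_input(images, model.input_size)
    opt = nn.SGD(model.net.params(), hp.learning_rate, hp.momentum, hp.weight_decay)
    rng = np.random.default_rng(hp.seed)
    history: list[dict] = []
    n = x.shape[0]
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            logits = model.net.forward(x[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, labels[idx])
            model.net.backward(dlogits)
            opt.step(model.net.grads())
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "accuracy": correct / n})
    return history


def grad_cam(model: CnnModel, image, target_class: int = 1,
             weights: str = "mean", target: str = "logit") -> Heatmap:
    """Gradient-weighted class activation heatmap for one scattergram.

    With the default ``weights="mean"`` this is classic Grad-CAM:
    alpha_k = spatial mean of d(score)/d(A_k) over the hooked feature map A,
    map = ReLU(sum_k alpha_k A_k).  With ``weights="elementwise"`` the
    gradient is kept spatially resolved, map = ReLU(sum_k dA_k * A_k) —
    the exact first-order decomposition of the score over locations, which
    stays class-discriminative for small networks whose fully connected
    head weights locations unevenly (channel-averaged weights are only
    reliable for deep, wide stacks whose channels are region-specific).

    ``target`` picks the scalar being differentiated: the raw class logit
    (``"logit"``) or the logit margin over the other class (``"margin"``).
    Either way the map is upsampled bilinearly to the input resolution and
    divided by its max (an all-zero map stays all zero).
    """
    if model.hook_index < 0:
        raise ConfigurationError("model has no convolutional layer to hook")
    if weights not in ("mean", "elementwise"):
        raise ConfigurationError(f"unknown weighting {weights!r}")
    if target not in ("logit", "margin"):
        raise ConfigurationError(f"unknown target {target!r}")
    view = None
    sample = image
    if isinstance(image, ScattergramImage):
        view = image.view
        sample = image.pixels
    x = _to_input(sample, model.input_size)
    # forward with caches, capturing A at the hook layer
    a = x
    for layer in model.net.layers[: model.hook_index + 1]:
        a = layer.forward(a, train=True)
    fmap = a
    logits = model.net.forward_from(fmap, model.hook_index + 1, train=True)
    seed_grad = np.zeros_like(logits)
    seed_grad[:, target_class] = 1.0
    if target == "margin":
        seed_grad[:, 1 - target_class] = -1.0
    d_fmap = model.net.backward(seed_grad, stop=model.hook_index + 1)
    if weights == "mean":
        alpha = d_fmap.mean(axis=(1, 2))                  # (1, K) over space
        cam = np.maximum((alpha[:, None, None, :] * fmap).sum(axis=-1), 0.0)[0]
    else:
        cam = np.maximum((d_fmap * fmap).sum(axis=-1), 0.0)[0]
    cam = cam.astype(np.float64)
    if cam.shape != (model.input_size, model.input_size):
        cam = _sk_resize(cam, (model.input_size, model.input_size), order=1,
                         preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    mx = cam.max()
    if mx > 0:
        cam = cam / mx
    return Heatmap(cam, view, target_class)


def extract_rois(heatmap: Heatmap | np.ndarray, threshold: float = 0.5,
                 min_area: int = 20) -> ROISet:
    """Binarize at ``threshold``, keep 8-connected components with at least
    ``min_area`` pixels, sorted by area descending."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    binary = values >= threshold
    labeled = measure.label(binary, connectivity=2)
    masks = []
    for lab in range(1, labeled.max() + 1):
        m = labeled == lab
        area = int(m.sum())
        if area >= min_area:
            masks.append(m)
    masks.sort(key=lambda m: -int(m.sum()))
    return ROISet(masks, threshold, min_area)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: CnnModel, path) -> None:
    arrays = {f"p{i}": p for i, p in enumerate(model.net.params())}
    meta = {"arch": model.arch, "seed": model.seed,
            "input_size": model.input_size, "view_name": model.view_name}
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> CnnModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["_meta"]))
    model = build_cnn(meta["arch"], meta["seed"], meta["input_size"],
                      view_name=meta["view_name"])
    for i, p in enumerate(model.net.params()):
        p[...] = data[f"p{i}"]
    return model
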
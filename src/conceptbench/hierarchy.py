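"""A small trainable convolutional hierarchy with named feature taps.

The model is a three-stage convolutional network (3x3 conv -> ReLU -> 2x2
max-pool per stage) followed by one fully connected "concept" layer with one
unit per base category. It is trained by momentum SGD on softmax
cross-entropy with a stepped learning-rate decay (lr after k completed decay
intervals = lr0 * (1 - decay)^k).

Four taps expose activations at increasing depth:

- ``Generic3``: stage-1 (earliest) activations, spatially average-pooled to a
  coarse grid — local edge/texture energy, position-sensitive.
- ``Generic2``: stage-2 activations, average-pooled likewise.
- ``Generic1``: stage-3 activations globally average-pooled — the last
  category-agnostic representation before any fully connected layer.
- ``Conceptual``: the pre-softmax output of the concept layer — one broadly
  tuned evidence value per *previously learned* category. The softmax itself
  is never applied at extraction time; the decision layer's sharpening is
  exactly what these features are meant to avoid.

Earlier taps keep spatial layout (more features, less invariance); later taps
are more invariant and more category-sensitive. Everything is plain numpy;
forward, backward and the optimizer are implemented here so training is
deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .synthetic_world import ImageDataset

__all__ = [
    "HierarchyConfig",
    "TrainedHierarchy",
    "FeatureMatrix",
    "TAPS",
    "preprocess",
    "train_hierarchy",
    "evaluate_topk",
    "extract_features",
    "combine_feature_sets",
    "category_selectivity",
    "save_checkpoint",
    "load_checkpoint",
]

TAPS = ("Conceptual", "Generic1", "Generic2", "Generic3")
FEATURE_SETS = TAPS + ("Generic1+Conceptual",)


@dataclass(frozen=True)
class HierarchyConfig:
    """Architecture and optimization settings.

    ``concept_width`` must equal the number of base categories — the concept
    layer has exactly one unit per previously learned category.
    ``decay_interval`` counts images seen between learning-rate decays;
    ``None`` means once per epoch.
    """

    input_size: int = 32
    stage_widths: tuple[int, int, int] = (16, 32, 64)
    concept_width: int = 30
    lr0: float = 0.01
    lr_decay_fraction: float = 0.04
    decay_interval: int | None = None
    momentum: float = 0.9
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lr_decay_fraction < 1.0:
            raise ValueError("lr_decay_fraction must be in (0, 1)")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if len(self.stage_widths) != 3:
            raise ValueError("exactly three convolutional stages are supported")
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (three 2x2 pools)")


def learning_rate(config: HierarchyConfig, images_seen: int, images_per_epoch: int) -> float:
    """Stepped schedule: lr0 * (1 - decay)^k after k completed intervals."""
    interval = config.decay_interval or images_per_epoch
    k = images_seen // interval
    return config.lr0 * (1.0 - config.lr_decay_fraction) ** k


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(
    image: np.ndarray,
    target_size: int,
    crop_mode: str = "center",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Shortest-edge resize preserving aspect ratio, then a square crop.

    ``crop_mode='random'`` (training) places the crop uniformly; ``'center'``
    (evaluation and feature extraction) removes equal margins.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape
    short = min(h, w)
    if short != target_size:
        from skimage.transform import resize

        scale = target_size / short
        nh, nw = round(h * scale), round(w * scale)
        nh, nw = max(nh, target_size), max(nw, target_size)
        image = resize(image, (nh, nw), anti_aliasing=scale < 1, preserve_range=True).astype(
            np.float32
        )
        h, w = nh, nw
    if crop_mode == "center":
        top, left = (h - target_size) // 2, (w - target_size) // 2
    elif crop_mode == "random":
        if rng is None:
            raise ValueError("random crop requires an rng")
        top = int(rng.integers(0, h - target_size + 1))
        left = int(rng.integers(0, w - target_size + 1))
    else:
        raise ValueError(f"unknown crop_mode {crop_mode!r}")
    return image[top : top + target_size, left : left + target_size]


def _preprocess_stack(
    images: np.ndarray, target_size: int, crop_mode: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    if images.shape[1] == images.shape[2] == target_size:
        return images  # already canvas-sized; crop/resize are identities
    return np.stack([preprocess(im, target_size, crop_mode, rng) for im in images])


# ---------------------------------------------------------------------------
# layers (im2col convolution, manual backprop)

def _im2col(x: np.ndarray) -> np.ndarray:
    # x: (N, C, H, W), 3x3 kernel, pad 1 -> (N, C*9, H*W)
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * 9, h * w)


_DTYPE = np.float32  # training precision; plenty for SGD at this scale


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 first_layer: bool = False):
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.first_layer = first_layer  # no input gradient needed

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        n, _, h, w = x.shape
        y = np.matmul(self.W[None], self._cols) + self.b[None, :, None]
        return y.reshape(n, -1, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        n, c, h, w = self._shape
        dyf = dy.reshape(n, -1, h * w)
        self.dW = np.matmul(dyf, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.db = dyf.sum(axis=(0, 2))
        if self.first_layer:
            return None
        dcols = np.matmul(self.W.T[None], dyf).reshape(n, c, 3, 3, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=dy.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, 1 : h + 1, 1 : w + 1]

    @property
    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        return (
            flat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


def _avgpool_grid(x: np.ndarray, out_grid: int) -> np.ndarray:
    """Average-pool (N, C, H, W) down to an out_grid x out_grid spatial map."""
    n, c, h, w = x.shape
    k = h // out_grid
    return x.reshape(n, c, out_grid, k, out_grid, k).mean(axis=(3, 5))


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(_DTYPE)
        self.b = np.zeros(d_out, dtype=_DTYPE)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _ConvNet:
    """Three conv stages + concept layer, exposing intermediate activations."""

    TAP_GRID = 4  # spatial grid kept by the Generic2/Generic3 average pools

    def __init__(self, config: HierarchyConfig):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
        w1, w2, w3 = config.stage_widths
        self.conv = [
            _Conv3x3(1, w1, rng, first_layer=True),
            _Conv3x3(w1, w2, rng),
            _Conv3x3(w2, w3, rng),
        ]
        self.relu = [_ReLU(), _ReLU(), _ReLU()]
        self.pool = [_MaxPool2(), _MaxPool2(), _MaxPool2()]
        self.fc = _Linear(w3, config.concept_width, rng)
        self.config = config

    def forward(self, x: np.ndarray, want_taps: bool = False):
        """x: (N, H, W) in [0,1] -> logits (N, concept_width).

        With ``want_taps`` also returns the tap activations dict.
        """
        a = np.ascontiguousarray(x[:, None, :, :], dtype=_DTYPE)
        stages = []
        for conv, relu, pool in zip(self.conv, self.relu, self.pool):
            a = pool.forward(relu.forward(conv.forward(a)))
            stages.append(a)
        gap = stages[2].mean(axis=(2, 3))  # (N, w3)
        self._gap_shape = stages[2].shape
        logits = self.fc.forward(gap)
        if not want_taps:
            return logits
        n = x.shape[0]
        taps = {
            "Conceptual": logits,
            "Generic1": gap,
            "Generic2": _avgpool_grid(stages[1], self.TAP_GRID).reshape(n, -1),
            "Generic3": _avgpool_grid(stages[0], self.TAP_GRID).reshape(n, -1),
        }
        return logits, taps

    def backward(self, dlogits: np.ndarray) -> None:
        dgap = self.fc.backward(dlogits)
        n, c, h, w = self._gap_shape
        da = np.broadcast_to(dgap[:, :, None, None] / (h * w), self._gap_shape).copy()
        for conv, relu, pool in zip(self.conv[::-1], self.relu[::-1], self.pool[::-1]):
            da = conv.backward(relu.backward(pool.backward(da)))

    def layers_with_params(self):
        return [*self.conv, self.fc]

    def tap_dims(self) -> dict[str, int]:
        w1, w2, w3 = self.config.stage_widths
        g = self.TAP_GRID * self.TAP_GRID
        return {
            "Conceptual": self.config.concept_width,
            "Generic1": w3,
            "Generic2": w2 * g,
            "Generic3": w1 * g,
        }


@dataclass
class TrainedHierarchy:
    net: _ConvNet
    config: HierarchyConfig
    label_order: list[str]  # concept-layer unit i scores label_order[i]
    training_log: list[dict] = field(default_factory=list)

    @property
    def tap_registry(self) -> dict[str, str]:
        return {
            "Conceptual": "concept fully connected layer, pre-softmax",
            "Generic1": "stage-3 activations, global average pool",
            "Generic2": "stage-2 activations, 4x4 average pool",
            "Generic3": "stage-1 activations, 4x4 average pool",
        }


@dataclass
class FeatureMatrix:
    """Images x features activations from one tap (or a concatenation)."""

    values: np.ndarray
    image_ids: list[str]
    labels: list[str]
    tap: str

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.image_ids) or len(self.image_ids) != len(self.labels):
            raise ValueError("row count must equal image id and label counts")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")
        if self.tap not in FEATURE_SETS:
            raise ValueError(f"tap must be one of {FEATURE_SETS}, got {self.tap!r}")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.values, columns=[f"f{i:03d}" for i in range(self.dim)]
        )
        df.insert(0, "label", self.labels)
        df.insert(0, "image_id", self.image_ids)
        return df


# ---------------------------------------------------------------------------
# training

def _softmax_xent(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    n = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1))
    loss = float(np.mean(logz - shifted[np.arange(n), targets]))
    p = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
    p[np.arange(n), targets] -= 1.0
    return loss, p / n


def train_hierarchy(
    base_train: ImageDataset,
    base_val: ImageDataset,
    config: HierarchyConfig,
    verbose: bool = False,
) -> TrainedHierarchy:
    """Train the hierarchy on the base categories with momentum SGD.

    Raises before training if the two datasets' label sets differ or if
    ``concept_width`` does not equal the number of base categories. Training
    uses random crops; validation uses center crops. The per-epoch training
    log records top-1 and top-5 accuracy on ``base_val``.
    """
    train_labels = sorted(base_train.label_set)
    if set(train_labels) != base_val.label_set:
        raise ValueError("base_train and base_val must share the same label set")
    if config.concept_width != len(train_labels):
        raise ValueError(
            f"concept_width ({config.concept_width}) must equal the number of base "
            f"categories ({len(train_labels)})"
        )

    label_to_idx = {lab: i for i, lab in enumerate(train_labels)}
    y = np.array([label_to_idx[lab] for lab in base_train.labels])
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 12]))

    net = _ConvNet(config)
    model = TrainedHierarchy(net=net, config=config, label_order=train_labels)

    x_all = _preprocess_stack(base_train.images, config.input_size, "random", rng)
    n = x_all.shape[0]
    velocity = {}
    images_seen = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            lr = learning_rate(config, images_seen, n)
            logits = net.forward(x_all[idx])
            loss, dlogits = _softmax_xent(logits, y[idx])
            net.backward(dlogits)
            for li, layer in enumerate(net.layers_with_params()):
                for pname, p, g in layer.params:
                    key = (li, pname)
                    v = velocity.get(key, 0.0)
                    v = config.momentum * v - lr * g
                    velocity[key] = v
                    p += v
            epoch_loss += loss * len(idx)
            images_seen += len(idx)
        top1 = evaluate_topk(model, base_val, 1)
        top5 = evaluate_topk(model, base_val, min(5, config.concept_width))
        model.training_log.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / n,
                "lr": learning_rate(config, images_seen, n),
                "top1": top1,
                "top5": top5,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {epoch_loss / n:.4f}  "
                f"top1 {top1:.3f}  top5 {top5:.3f}"
            )
    return model


def _forward_batched(model: TrainedHierarchy, images: np.ndarray, want_taps: bool,
                     batch: int = 256):
    outs, taps_acc = [], []
    for start in range(0, images.shape[0], batch):
        chunk = images[start : start + batch]
        if want_taps:
            logits, taps = model.net.forward(chunk, want_taps=True)
            taps_acc.append(taps)
        else:
            logits = model.net.forward(chunk)
        outs.append(logits)
    logits = np.concatenate(outs)
    if not want_taps:
        return logits
    merged = {k: np.concatenate([t[k] for t in taps_acc]) for k in taps_acc[0]}
    return logits, merged


def evaluate_topk(model: TrainedHierarchy, dataset: ImageDataset, k: int) -> float:
    """Fraction of images whose true label is among the k highest scores.

    Ties are broken by concept-unit index (stable descending sort), so the
    metric is deterministic. Only base-label datasets are accepted.
    """
    if dataset.role == "novel":
        raise ValueError("top-k accuracy is defined over base labels only")
    extra = dataset.label_set - set(model.label_order)
    if extra:
        raise ValueError(f"dataset labels outside the model's base set: {sorted(extra)[:5]}")
    if not 1 <= k <= model.config.concept_width:
        raise ValueError("k must be in [1, concept_width]")
    x = _preprocess_stack(dataset.images, model.config.input_size, "center")
    logits = _forward_batched(model, x, want_taps=False)
    ranking = np.argsort(-logits, axis=1, kind="stable")[:, :k]
    idx = np.array([model.label_order.index(lab) for lab in dataset.labels])
    return float(np.mean((ranking == idx[:, None]).any(axis=1)))


def extract_features(model: TrainedHierarchy, dataset: ImageDataset, tap: str) -> FeatureMatrix:
    """Extract one tap's activations for every image (center crop).

    ``Conceptual`` rows are pre-softmax concept-layer scores. Deterministic
    given the model and dataset.
    """
    if tap not in TAPS:
        raise ValueError(f"unknown tap {tap!r}; registered taps: {TAPS}")
    x = _preprocess_stack(dataset.images, model.config.input_size, "center")
    _, taps = _forward_batched(model, x, want_taps=True)
    return FeatureMatrix(
        values=taps[tap],
        image_ids=list(dataset.image_ids),
        labels=list(dataset.labels),
        tap=tap,
    )


def combine_feature_sets(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of two taps over identical images."""
    if a.image_ids != b.image_ids:
        raise ValueError("feature matrices cover different images or orderings")
    return FeatureMatrix(
        values=np.concatenate([a.values, b.values], axis=1),
        image_ids=list(a.image_ids),
        labels=list(a.labels),
        tap="Generic1+Conceptual",
    )


def category_selectivity(features: FeatureMatrix) -> float:
    """Mean per-feature between-category / within-category variance ratio.

    Higher values mean individual features are more reliable signals of
    category membership. Deeper taps should score higher.
    """
    labels = np.asarray(features.labels)
    cats = np.unique(labels)
    means = np.stack([features.values[labels == c].mean(axis=0) for c in cats])
    within = np.stack([features.values[labels == c].var(axis=0) for c in cats]).mean(axis=0)
    between = means.var(axis=0)
    return float(np.mean(between / (within + 1e-12)))


# ---------------------------------------------------------------------------
# checkpoint I/O: one .npz parameter container + JSON sidecar

def save_checkpoint(model: TrainedHierarchy, path: str | Path) -> None:
    path = Path(path)
    arrays = {}
    for li, layer in enumerate(model.net.layers_with_params()):
        arrays[f"L{li}_W"] = layer.W
        arrays[f"L{li}_b"] = layer.b
    np.savez(path, **arrays)
    sidecar = {
        "config": asdict(model.config),
        "label_order": model.label_order,
        "tap_registry": model.tap_registry,
        "training_log": model.training_log,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_checkpoint(path: str | Path) -> TrainedHierarchy:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg_d = sidecar["config"]
    cfg_d["stage_widths"] = tuple(cfg_d["stage_widths"])
    config = HierarchyConfig(**cfg_d)
    net = _ConvNet(config)
    with np.load(path) as z:
        for li, layer in enumerate(net.layers_with_params()):
            layer.W[...] = z[f"L{li}_W"]
            layer.b[...] = z[f"L{li}_b"]
    return TrainedHierarchy(
        net=net,
        config=config,
        label_order=list(sidecar["label_order"]),
        training_log=list(sidecar["training_log"]),
    )
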
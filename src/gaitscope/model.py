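"""A small 1D convolutional network for 4x128 accelerometer epochs.

The network is implemented directly on NumPy arrays (im2col-style
convolutions, Adam, early stopping) rather than on a deep-learning framework.
Keeping the layer graph explicit has a second purpose: relevance propagation
(:mod:`gaitscope.relprop`) walks the same ``ModelGraph`` structure, layer by
layer, with access to every activation, weight and bias.

Constraints baked in:

* input is a 4-channel, 128-sample epoch;
* all hidden activations are ReLU (positive, monotone — required by the
  relevance rules);
* the terminal layer is a softmax over the label space; relevance and the
  loss both operate on the pre-softmax logits.

Default architecture: conv1d(32, 9) - relu - maxpool(2) - conv1d(64, 5) -
relu - maxpool(2) - flatten - dense(100) - relu - dense(n_classes) - softmax.
The layer sizes are deliberately small so that full training runs in minutes
on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocessing import EPOCH_SAMPLES, EpochDataset

__all__ = [
    "Conv1D", "ReLU", "MaxPool1D", "Flatten", "Dense", "Softmax",
    "ModelGraph", "TrainConfig", "Prediction",
    "build_dcnn", "train", "predict_epoch", "predict_proba",
    "DEFAULT_ARCH",
]

N_CHANNELS = 4

DEFAULT_ARCH = (
    ("conv1d", {"filters": 32, "kernel": 9}),
    ("relu", {}),
    ("maxpool1d", {"size": 2}),
    ("conv1d", {"filters": 64, "kernel": 5}),
    ("relu", {}),
    ("maxpool1d", {"size": 2}),
    ("flatten", {}),
    ("dense", {"units": 100}),
    ("relu", {}),
    ("dense", {"units": None}),   # None -> |label_space|
    ("softmax", {}),
)


class Layer:
    kind = "layer"
    trainable = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv1D(Layer):
    """Valid (no padding), stride-1 cross-correlation along time.

    ``w`` has shape (out_channels, in_channels, kernel); input (B, C, L).
    """

    kind = "conv1d"

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, use_bias: bool = True):
        fan_in = in_channels * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.use_bias = use_bias
        self._x = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        win = sliding_window_view(x, self.w.shape[2], axis=2)  # (B,C,Lo,k)
        y = np.einsum("bclk,ock->bol", win, self.w, optimize=True)
        if self.use_bias:
            y = y + self.b[None, :, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, k = self._x, self.w.shape[2]
        win = sliding_window_view(x, k, axis=2)
        self.dw = np.einsum("bclk,bol->ock", win, dy, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
        wrev = self.w[:, :, ::-1]
        dwin = sliding_window_view(dyp, k, axis=2)  # (B,O,L,k)
        return np.einsum("bolk,ock->bcl", dwin, wrev, optimize=True)

    def params(self):
        return {"w": self.w, "b": self.b} if self.use_bias else {"w": self.w}

    def grads(self):
        return {"w": self.dw, "b": self.db} if self.use_bias else {"w": self.dw}


class ReLU(Layer):
    kind = "relu"
    trainable = False

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    kind = "maxpool1d"
    trainable = False

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x):
        b, c, n = x.shape
        lo = n // self.size
        self._in_shape = x.shape
        xr = x[:, :, :lo * self.size].reshape(b, c, lo, self.size)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy):
        b, c, n = self._in_shape
        lo = n // self.size
        dx = np.zeros((b, c, lo, self.size))
        bi, ci, li = np.meshgrid(np.arange(b), np.arange(c), np.arange(lo),
                                 indexing="ij")
        dx[bi, ci, li, self._argmax] = dy
        out = np.zeros(self._in_shape)
        out[:, :, :lo * self.size] = dx.reshape(b, c, lo * self.size)
        return out


class Flatten(Layer):
    kind = "flatten"
    trainable = False

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Affine map; ``w`` has shape (in_features, units)."""

    kind = "dense"

    def __init__(self, in_features: int, units: int, rng: np.random.Generator,
                 use_bias: bool = True):
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                            size=(in_features, units))
        self.b = np.zeros(units)
        self.use_bias = use_bias
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        y = x @ self.w
        if self.use_bias:
            y = y + self.b
        return y

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return {"w": self.w, "b": self.b} if self.use_bias else {"w": self.w}

    def grads(self):
        return {"w": self.dw, "b": self.db} if self.use_bias else {"w": self.dw}


class Softmax(Layer):
    kind = "softmax"
    trainable = False

    def forward(self, x):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, dy):  # pragma: no cover - loss works on logits
        raise RuntimeError("softmax backward is folded into the loss")


@dataclass
class Prediction:
    """Per-epoch output: probability simplex, logits, argmax label."""

    probabilities: np.ndarray
    logits: np.ndarray
    label: str


class ModelGraph:
    """Ordered layer stack plus the label space it predicts over."""

    def __init__(self, layers: list[Layer], label_space: tuple[str, ...]):
        if not isinstance(layers[-1], Softmax):
            raise ValueError("terminal layer must be softmax")
        if sum(isinstance(l, Softmax) for l in layers) != 1:
            raise ValueError("exactly one softmax layer allowed")
        self.layers = layers
        self.label_space = tuple(label_space)

    # -- forward ------------------------------------------------------------

    def logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers[:-1]:
            x = layer.forward(x)
        return x

    def forward_with_cache(self, x: np.ndarray) -> list[np.ndarray]:
        """Activations entering each non-softmax layer, plus the final logits."""
        acts = [x]
        for layer in self.layers[:-1]:
            x = layer.forward(x)
            acts.append(x)
        return acts

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.layers[-1].forward(self.logits(x))

    # -- bookkeeping --------------------------------------------------------

    @property
    def parametric_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params()]

    def set_frozen(self, frozen_indices: set[int]) -> None:
        for i in frozen_indices:
            if i < 0 or i >= len(self.layers):
                raise ValueError(f"no layer at index {i}")
        for i, layer in enumerate(self.layers):
            if layer.params():
                layer.trainable = i not in frozen_indices

    def copy(self) -> "ModelGraph":
        import copy
        return copy.deepcopy(self)

    def state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params().items()}
                for l in self.parametric_layers]

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, st in zip(self.parametric_layers, state):
            for k, v in st.items():
                layer.params()[k][...] = v

    # -- serialisation ------------------------------------------------------

    def describe(self) -> list[dict]:
        desc = []
        for l in self.layers:
            d = {"kind": l.kind}
            if isinstance(l, Conv1D):
                d.update(filters=l.w.shape[0], in_channels=l.w.shape[1],
                         kernel=l.w.shape[2], use_bias=l.use_bias)
            elif isinstance(l, Dense):
                d.update(in_features=l.w.shape[0], units=l.w.shape[1],
                         use_bias=l.use_bias)
            elif isinstance(l, MaxPool1D):
                d.update(size=l.size)
            desc.append(d)
        return desc

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, l in enumerate(self.layers):
            for k, v in l.params().items():
                arrays[f"layer{i}_{k}"] = v
        np.savez_compressed(path, **arrays)
        meta = {"label_space": list(self.label_space), "layers": self.describe()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelGraph":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        rng = np.random.default_rng(0)
        layers: list[Layer] = []
        for d in meta["layers"]:
            kind = d["kind"]
            if kind == "conv1d":
                layers.append(Conv1D(d["in_channels"], d["filters"], d["kernel"],
                                     rng, d["use_bias"]))
            elif kind == "dense":
                layers.append(Dense(d["in_features"], d["units"], rng,
                                    d["use_bias"]))
            elif kind == "relu":
                layers.append(ReLU())
            elif kind == "maxpool1d":
                layers.append(MaxPool1D(d["size"]))
            elif kind == "flatten":
                layers.append(Flatten())
            elif kind == "softmax":
                layers.append(Softmax())
        model = cls(layers, tuple(meta["label_space"]))
        z = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        for i, l in enumerate(model.layers):
            for k in l.params():
                l.params()[k][...] = z[f"layer{i}_{k}"]
        return model


def build_dcnn(label_space: tuple[str, ...],
               arch: tuple = DEFAULT_ARCH,
               rng_seed: int = 0,
               use_bias: bool = True,
               input_length: int = EPOCH_SAMPLES) -> ModelGraph:
    """Assemble a ModelGraph, propagating shapes symbolically.

    Any ReLU-only stack of the supported layer kinds is accepted; a hidden
    activation other than ReLU is rejected because the downstream relevance
    rules assume positive, monotonically increasing activations.
    """
    label_space = tuple(label_space)
    if len(label_space) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(rng_seed)
    layers: list[Layer] = []
    shape: tuple = (N_CHANNELS, input_length)
    for kind, p in arch:
        if kind == "conv1d":
            if len(shape) != 2:
                raise ValueError("conv1d after flatten is unsupported")
            c, n = shape
            k = p["kernel"]
            if n < k:
                raise ValueError(f"kernel {k} exceeds length {n}")
            layers.append(Conv1D(c, p["filters"], k, rng, use_bias))
            shape = (p["filters"], n - k + 1)
        elif kind == "relu":
            layers.append(ReLU())
        elif kind == "maxpool1d":
            c, n = shape
            layers.append(MaxPool1D(p["size"]))
            shape = (c, n // p["size"])
        elif kind == "flatten":
            layers.append(Flatten())
            shape = (int(np.prod(shape)),)
        elif kind == "dense":
            if len(shape) != 1:
                raise ValueError("dense requires flattened input")
            units = p["units"] if p["units"] is not None else len(label_space)
            layers.append(Dense(shape[0], units, rng, use_bias))
            shape = (units,)
        elif kind == "softmax":
            layers.append(Softmax())
        elif kind in ("tanh", "sigmoid", "elu", "gelu"):
            raise ValueError(
                f"hidden activation {kind!r} rejected: relevance rules require ReLU")
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
    return ModelGraph(layers, label_space)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.10
    rng_seed: int = 0


class _Adam:
    def __init__(self, model: ModelGraph, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params().items()}
                  for l in model.parametric_layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params().items()}
                  for l in model.parametric_layers]

    def step(self, model: ModelGraph) -> None:
        self.t += 1
        for i, layer in enumerate(model.parametric_layers):
            if not layer.trainable:
                continue
            grads = layer.grads()
            for k, p in layer.params().items():
                g = grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1 ** self.t)
                vhat = self.v[i][k] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(y_idx)
    loss = -logp[np.arange(n), y_idx].mean()
    dlogits = np.exp(logp)
    dlogits[np.arange(n), y_idx] -= 1.0
    return float(loss), dlogits / n


def _label_indices(model: ModelGraph, labels: np.ndarray) -> np.ndarray:
    lut = {lab: i for i, lab in enumerate(model.label_space)}
    try:
        return np.array([lut[l] for l in labels])
    except KeyError as e:  # pragma: no cover
        raise ValueError(f"label {e} outside model label space") from e


def _subject_val_split(dataset: EpochDataset, fraction: float,
                       rng: np.random.Generator) -> tuple[EpochDataset, EpochDataset]:
    """Hold out ~`fraction` of the data as validation, subject-wise per class."""
    subjects = dataset.subjects
    val_subjects: list[str] = []
    for cls in dataset.label_space:
        cls_subj = np.unique(dataset.subject_ids[dataset.labels == cls])
        if cls_subj.size == 0:
            continue
        n_val = max(1, int(round(fraction * cls_subj.size)))
        n_val = min(n_val, cls_subj.size - 1) if cls_subj.size > 1 else 0
        if n_val:
            val_subjects.extend(rng.choice(cls_subj, size=n_val, replace=False))
    if not val_subjects:
        # single-subject classes: fall back to a random epoch split
        idx = rng.permutation(len(dataset))
        n_val = max(1, int(round(fraction * len(dataset))))
        vmask = np.zeros(len(dataset), dtype=bool)
        vmask[idx[:n_val]] = True
        return dataset.subset(~vmask), dataset.subset(vmask)
    vmask = np.isin(dataset.subject_ids, val_subjects)
    return dataset.subset(~vmask), dataset.subset(vmask)


def train(model: ModelGraph, dataset: EpochDataset,
          cfg: TrainConfig = TrainConfig(),
          val_dataset: EpochDataset | None = None,
          ) -> tuple[ModelGraph, dict[str, list[float]]]:
    """Minimise cross-entropy with Adam; early-stop on validation loss.

    Returns the model restored to its best-validation weights plus the
    training history. Fully deterministic for a given config seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("training data contains a single class")
    if cfg.optimizer != "adam":
        raise ValueError("only adam is implemented")
    rng = np.random.default_rng(cfg.rng_seed)
    if val_dataset is None:
        dataset, val_dataset = _subject_val_split(dataset, cfg.val_fraction, rng)

    y = _label_indices(model, dataset.labels)
    yv = _label_indices(model, val_dataset.labels)
    opt = _Adam(model, cfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [],
                                       "val_best": []}
    best_loss, best_state, since_best = np.inf, model.state(), 0

    for _ in range(cfg.max_epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            logits = model.logits(dataset.X[idx])
            loss, dlogits = _cross_entropy(logits, y[idx])
            losses.append(loss)
            grad = dlogits
            for layer in reversed(model.layers[:-1]):
                grad = layer.backward(grad)
            opt.step(model)
        val_loss, _ = _cross_entropy(model.logits(val_dataset.X), yv)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, best_state, since_best = val_loss, model.state(), 0
        else:
            since_best += 1
        history["val_best"].append(best_loss)
        if since_best >= cfg.patience:
            break
    model.load_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# inference


def predict_proba(model: ModelGraph, X: np.ndarray,
                  batch_size: int = 512) -> np.ndarray:
    """Class probabilities for a stack of epochs, batched for memory."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    out = [model.predict_proba(X[s:s + batch_size])
           for s in range(0, len(X), batch_size)]
    return np.concatenate(out)


def predict_epoch(model: ModelGraph, epoch) -> Prediction:
    """Probabilities, logits and argmax label for one 4x128 epoch."""
    x = epoch.x if hasattr(epoch, "x") else np.asarray(epoch, dtype=float)
    if x.shape != (N_CHANNELS, EPOCH_SAMPLES):
        raise ValueError(f"expected (4, {EPOCH_SAMPLES}) input, got {x.shape}")
    logits = model.logits(x[None])[0]
    probs = model.layers[-1].forward(logits[None])[0]
    return Prediction(probabilities=probs, logits=logits,
                      label=model.label_space[int(np.argmax(probs))])
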
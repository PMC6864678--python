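"""Convolutional classifier for 7 x 837 excitation-emission matrices.

The network is deliberately small: one valid (no-padding) convolution layer
whose 7 x 7 filters span the full height of the input — seven excitation
channels — and slide only along the wavelength axis, producing 32 feature
maps of length 831; then a flattening layer (26592 features), one hidden
fully connected layer, and a 9-way softmax output.  ReLU follows the
convolution and every hidden dense layer.  There is *no* pooling layer: a
spectral feature is an amplitude relation between exact wavelengths, whose
location carries information, so down-sampling positions would discard
signal rather than nuisance.

Training minimizes the cross-entropy by plain stochastic gradient descent
(learning rate 0.1, no momentum by default).  Forward and backward passes
are written directly in numpy; the convolution is evaluated as a matrix
product against pre-extracted sliding-window patches, which are computed
once per dataset since the first layer's input never changes during
training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError
from .preprocess import ProcessedMatrix

__all__ = [
    "CNNSpec",
    "TrainingTrace",
    "ConvSpectraNet",
    "conv_output_length",
    "build_model",
    "train",
    "predict",
    "penultimate_features",
    "as_input_array",
]


def conv_output_length(input_width: int, filter_width: int, stride: int = 1) -> int:
    """Number of valid filter placements: floor((W - F)/S) + 1."""
    if filter_width > input_width:
        raise ParameterError(f"filter width {filter_width} exceeds input width {input_width}")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    return (input_width - filter_width) // stride + 1


@dataclass
class CNNSpec:
    """Architecture and training hyper-parameters."""

    input_rows: int = 7
    input_cols: int = 837
    n_filters: int = 32
    filter_rows: int = 7
    filter_cols: int = 7
    stride: int = 1
    hidden_fc_sizes: tuple[int, ...] = (128,)
    n_classes: int = 9
    learning_rate: float = 0.1
    momentum: float = 0.0
    epochs: int = 500
    batch_size: int | None = 18  # None = full batch (deterministic mode)
    balanced_batches: bool = True  # stratify each minibatch over the classes
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if self.filter_rows != self.input_rows:
            raise ConfigurationError(
                "filter must span the full input height (slides horizontally only): "
                f"filter_rows={self.filter_rows} != input_rows={self.input_rows}"
            )
        conv_output_length(self.input_cols, self.filter_cols, self.stride)
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.learning_rate < 0:
            raise ConfigurationError("learning rate must be >= 0")
        if self.dtype not in ("float32", "float64"):
            raise ConfigurationError("dtype must be 'float32' or 'float64'")

    @property
    def conv_length(self) -> int:
        return conv_output_length(self.input_cols, self.filter_cols, self.stride)

    @property
    def flat_size(self) -> int:
        return self.n_filters * self.conv_length


@dataclass
class TrainingTrace:
    """Per-epoch training/test accuracy and full-training-set cross-entropy (nats)."""

    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


def as_input_array(data, dtype=np.float32) -> np.ndarray:
    """Stack ProcessedMatrix values (or pass through an array) to (N, rows, cols)."""
    if isinstance(data, np.ndarray):
        arr = data
    else:
        arr = np.stack([m.values for m in data])
    if arr.ndim != 3:
        raise ParameterError(f"expected (n, rows, cols) input, got shape {arr.shape}")
    return np.ascontiguousarray(arr, dtype=dtype)


class ConvSpectraNet:
    """conv(n_filters, full-height, valid) -> ReLU -> flatten -> [FC -> ReLU]* -> FC -> softmax."""

    def __init__(self, spec: CNNSpec):
        spec.validate()
        self.spec = spec
        self.dtype = np.dtype(spec.dtype)
        self.classes_: list[str] | None = None
        rng = np.random.default_rng(spec.seed)
        # He-style uniform initialization, seeded
        fan_conv = spec.filter_rows * spec.filter_cols
        self.params: dict[str, np.ndarray] = {
            "Wc": self._he(rng, (spec.n_filters, fan_conv), fan_conv),
            "bc": np.zeros(spec.n_filters, dtype=self.dtype),
        }
        sizes = [spec.flat_size, *spec.hidden_fc_sizes, spec.n_classes]
        self.n_dense = len(sizes) - 1
        for i in range(self.n_dense):
            self.params[f"W{i}"] = self._he(rng, (sizes[i + 1], sizes[i]), sizes[i])
            self.params[f"b{i}"] = np.zeros(sizes[i + 1], dtype=self.dtype)
        self._velocity = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _he(self, rng: np.random.Generator, shape: tuple[int, int], fan_in: int) -> np.ndarray:
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=shape).astype(self.dtype)

    # -- patch extraction ---------------------------------------------------

    def extract_patches(self, X: np.ndarray) -> np.ndarray:
        """Sliding full-height windows of X (n, rows, cols) -> (n, L, rows*filter_cols)."""
        s = self.spec
        X = as_input_array(X, dtype=self.dtype)
        if X.shape[1] != s.input_rows or X.shape[2] != s.input_cols:
            raise ParameterError(
                f"input shape {X.shape[1:]} does not match spec "
                f"({s.input_rows}, {s.input_cols})"
            )
        win = np.lib.stride_tricks.sliding_window_view(X, s.filter_cols, axis=2)
        # (n, rows, L', cols_f) -> stride -> (n, L, rows, cols_f) -> (n, L, rows*cols_f)
        win = win[:, :, :: s.stride, :]
        patches = win.transpose(0, 2, 1, 3).reshape(X.shape[0], s.conv_length, -1)
        return np.ascontiguousarray(patches, dtype=self.dtype)

    # -- forward / backward -------------------------------------------------

    def _forward(self, patches: np.ndarray, need_cache: bool = False):
        s = self.spec
        n = patches.shape[0]
        zc = patches.reshape(n * s.conv_length, -1) @ self.params["Wc"].T + self.params["bc"]
        ac = np.maximum(zc, 0.0)
        acts = [ac.reshape(n, -1)]  # flatten: (n, L*n_filters)
        zs = [zc]
        for i in range(self.n_dense):
            z = acts[-1] @ self.params[f"W{i}"].T + self.params[f"b{i}"]
            zs.append(z)
            acts.append(np.maximum(z, 0.0) if i < self.n_dense - 1 else z)
        logits = acts[-1]
        if need_cache:
            return logits, (patches, zs, acts)
        return logits

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_gradients(self, patches: np.ndarray, y: np.ndarray):
        """Mean cross-entropy over the batch and gradients w.r.t. every parameter."""
        s = self.spec
        n = patches.shape[0]
        logits, (patches, zs, acts) = self._forward(patches, need_cache=True)
        probs = self._softmax(logits.astype(np.float64))
        loss = float(-np.mean(np.log(np.clip(probs[np.arange(n), y], 1e-300, None))))
        grads: dict[str, np.ndarray] = {}
        delta = probs.astype(self.dtype)
        delta[np.arange(n), y] -= 1.0
        delta /= n
        for i in range(self.n_dense - 1, -1, -1):
            grads[f"W{i}"] = delta.T @ acts[i]
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.params[f"W{i}"]) * (zs[i] > 0)
        dflat = (delta @ self.params["W0"]) if self.n_dense > 0 else delta
        dzc = (dflat.reshape(n * s.conv_length, s.n_filters)) * (zs[0] > 0)
        grads["Wc"] = dzc.T @ patches.reshape(n * s.conv_length, -1)
        grads["bc"] = dzc.sum(axis=0)
        return loss, grads

    def sgd_step(self, grads: dict[str, np.ndarray]) -> None:
        s = self.spec
        for k, g in grads.items():
            if s.momentum > 0:
                v = self._velocity[k]
                v *= s.momentum
                v -= s.learning_rate * g
                self.params[k] += v
            else:
                self.params[k] -= (s.learning_rate * g).astype(self.dtype)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X, chunk: int = 256) -> np.ndarray:
        X = as_input_array(X, dtype=self.dtype)
        out = []
        for i in range(0, X.shape[0], chunk):
            patches = self.extract_patches(X[i : i + chunk])
            out.append(self._softmax(self._forward(patches).astype(np.float64)))
        return np.vstack(out)

    def predict(self, X) -> tuple[list[str], np.ndarray]:
        probs = self.predict_proba(X)
        idx = probs.argmax(axis=1)
        if self.classes_ is None:
            labels = [str(i) for i in idx]
        else:
            labels = [self.classes_[i] for i in idx]
        return labels, probs

    def penultimate_features(self, X, chunk: int = 256) -> np.ndarray:
        """Post-ReLU activations of the last hidden dense layer (or the flatten
        layer if the network has no hidden dense layer)."""
        X = as_input_array(X, dtype=self.dtype)
        out = []
        for i in range(0, X.shape[0], chunk):
            patches = self.extract_patches(X[i : i + chunk])
            _, (_, zs, acts) = self._forward(patches, need_cache=True)
            out.append(acts[-2] if self.n_dense > 1 else acts[0])
        return np.vstack(out)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = {"spec": asdict(self.spec), "classes": self.classes_}
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "ConvSpectraNet":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            spec_d = meta["spec"]
            spec_d["hidden_fc_sizes"] = tuple(spec_d["hidden_fc_sizes"])
            model = cls(CNNSpec(**spec_d))
            model.classes_ = meta["classes"]
            for k in model.params:
                model.params[k] = data[k].astype(model.dtype)
        return model


def build_model(spec: CNNSpec | None = None) -> ConvSpectraNet:
    return ConvSpectraNet(spec or CNNSpec())


def _labels_to_indices(labels: list[str], classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.asarray([index[l] for l in labels])
    except KeyError as e:  # pragma: no cover
        raise ParameterError(f"unknown label {e}") from e


def train(
    model: ConvSpectraNet,
    train_set: list[ProcessedMatrix],
    test_set: list[ProcessedMatrix],
    spec: CNNSpec | None = None,
) -> TrainingTrace:
    """SGD training with a per-epoch accuracy/loss trace; reproducible given the seed.

    Minibatches are class-balanced by default (``balanced_batches``): each
    batch holds ``batch_size / n_classes`` samples of every class, which
    removes the class-composition component of the gradient noise — at a
    learning rate of 0.1 without momentum, that noise is otherwise large
    enough to keep plain shuffled batches from settling.  Balancing requires
    equal class counts and a batch size divisible by the class count;
    otherwise training falls back to plain shuffling.  With
    ``batch_size=None`` every epoch takes a single full-batch gradient step
    without shuffling (deterministic mode used by the gradient tests).
    """
    spec = spec or model.spec
    if not train_set or not test_set:
        raise ParameterError("training and test sets must be non-empty")
    classes = sorted({m.label for m in train_set})
    model.classes_ = classes
    y_train = _labels_to_indices([m.label for m in train_set], classes)
    y_test = _labels_to_indices([m.label for m in test_set], classes)

    Xtr = as_input_array(train_set, dtype=model.dtype)
    Xte = as_input_array(test_set, dtype=model.dtype)
    # first-layer input is constant: extract sliding windows once
    Ptr = model.extract_patches(Xtr)
    Pte = model.extract_patches(Xte)

    n = Ptr.shape[0]
    batch = n if spec.batch_size is None else min(spec.batch_size, n)
    counts = np.bincount(y_train, minlength=len(classes))
    balanced = (
        spec.balanced_batches
        and batch < n
        and batch % len(classes) == 0
        and np.all(counts == counts[0])
    )
    per_class = batch // len(classes) if balanced else 0
    class_indices = [np.nonzero(y_train == c)[0] for c in range(len(classes))]
    rng = np.random.default_rng(spec.seed + 1)  # batching stream, distinct from init
    trace = TrainingTrace()
    for _ in range(spec.epochs):
        if balanced:
            orders = [rng.permutation(ci) for ci in class_indices]
            n_batches = counts[0] // per_class
            batches = [
                np.concatenate([o[b * per_class : (b + 1) * per_class] for o in orders])
                for b in range(n_batches)
            ]
        else:
            order = np.arange(n) if batch >= n else rng.permutation(n)
            batches = [order[s : s + batch] for s in range(0, n, batch)]
        for idx in batches:
            loss, grads = model.loss_and_gradients(Ptr[idx], y_train[idx])
            # a cross-entropy of hundreds of nats means the softmax has
            # saturated on the wrong class — the optimizer blew up
            if not np.isfinite(loss) or loss > 100.0:
                raise RuntimeError(
                    f"training diverged (loss {loss:.3g}); learning rate "
                    f"{spec.learning_rate} is the likely cause"
                )
            model.sgd_step(grads)
        trace.loss.append(_full_loss(model, Ptr, y_train))
        trace.train_accuracy.append(_accuracy_from_patches(model, Ptr, y_train))
        trace.test_accuracy.append(_accuracy_from_patches(model, Pte, y_test))
    return trace


def _full_loss(model: ConvSpectraNet, patches: np.ndarray, y: np.ndarray, chunk: int = 512) -> float:
    total = 0.0
    for i in range(0, patches.shape[0], chunk):
        logits = model._forward(patches[i : i + chunk])
        probs = model._softmax(logits.astype(np.float64))
        p = np.clip(probs[np.arange(len(logits)), y[i : i + chunk]], 1e-300, None)
        total += float(-np.log(p).sum())
    return total / patches.shape[0]


def _accuracy_from_patches(model: ConvSpectraNet, patches: np.ndarray, y: np.ndarray, chunk: int = 512) -> float:
    hits = 0
    for i in range(0, patches.shape[0], chunk):
        logits = model._forward(patches[i : i + chunk])
        hits += int((logits.argmax(axis=1) == y[i : i + chunk]).sum())
    return hits / patches.shape[0]


def predict(model: ConvSpectraNet, matrices) -> tuple[list[str], np.ndarray]:
    """Predicted labels and softmax class probabilities (rows sum to 1)."""
    return model.predict(matrices)


def penultimate_features(model: ConvSpectraNet, matrices) -> np.ndarray:
    """Activations of the last hidden layer, for PCA score-plot visualization."""
    import warnings

    if model.classes_ is None:
        warnings.warn("model has not been trained; features come from the random initialization")
    return model.penultimate_features(matrices)
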
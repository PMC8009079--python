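"""The convolutional classifier for HAR-Images, implemented in numpy.

Two routes through the same mathematics live here deliberately:

* **Reference ops** (:func:`conv2d_multichannel`, :func:`maxpool`,
  :func:`flatten_concat`, :func:`dense_forward`, :func:`softmax`) evaluate the
  forward-pass definitions naively, with explicit loops where that keeps the
  code a transparent transcription of the math.  They exist to be read and to
  serve as oracles.
* **The trainable model** (:func:`build_model`, :func:`train`,
  :func:`predict`) is a fast batched implementation with backpropagation and
  Adam, verified against the reference ops in the test suite.

The default architecture is small: two convolutional layers with 2 and 4
filters of size 2x2 ("same" padding, ReLU), each followed by 2x2 max-pooling,
then dense layers of 48 and 24 units with dropout 0.5 after each, and a
softmax output over the six activity classes.  On 40x40x3 inputs the spatial
size goes 40 -> 40 -> 20 -> 20 -> 10, giving a 400-dimensional flattened
feature vector.  Training minimizes sparse categorical cross-entropy.

Convolution is cross-correlation (no kernel flip), matching the index
arithmetic of the defining equation and standard deep-learning convention.
"Same" padding at stride 1 preserves the spatial size; when the required
total padding is odd the extra zero goes at the bottom/right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Reference forward-pass operations (naive, loop-level transcriptions)
# ---------------------------------------------------------------------------


def conv_output_shape(input_size: int, filter_size: int, padding: int, stride: int) -> int:
    """Spatial output size of a convolution: (mu - a + 2P)/S + 1.

    When the stride does not divide (mu - a + 2P) the result is floored,
    i.e. the filter never overhangs the padded input.
    """
    if min(input_size, filter_size, stride) < 1 or padding < 0:
        raise ValueError("sizes and stride must be positive, padding non-negative")
    out = (input_size - filter_size + 2 * padding) // stride + 1
    if out < 1:
        raise ValueError(
            f"filter of size {filter_size} does not fit input of size "
            f"{input_size} with padding {padding}"
        )
    return out


def same_padding(filter_size: int) -> tuple[int, int]:
    """(before, after) zero padding that preserves size at stride 1.

    Total padding is ``filter_size - 1``; when odd, the extra zero goes after
    (bottom/right).
    """
    total = filter_size - 1
    return total // 2, total - total // 2


def conv2d_multichannel(
    X: np.ndarray,
    kernels: np.ndarray,
    stride: tuple[int, int] = (1, 1),
    padding: int = 0,
) -> np.ndarray:
    """Multi-channel 2D cross-correlation, summed over input channels.

    Direct evaluation of the per-channel convolution
    ``Y[i, j] = sum_c sum_p sum_q K[p, q, c] * X[i + p, j + q, c]``
    (padded, strided), i.e. each channel is correlated with its own kernel
    slice and the channel outputs are summed element-wise.

    ``X`` is (H, W, C); ``kernels`` is (a, b, C) for a single output map or
    (a, b, C, F) for F filters, giving an (Ho, Wo) or (Ho, Wo, F) output.
    This is the readable reference implementation used as an oracle.
    """
    X = np.asarray(X, dtype=float)
    K = np.asarray(kernels, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must be (H, W, C)")
    single = K.ndim == 3
    if single:
        K = K[..., None]
    if K.ndim != 4 or K.shape[2] != X.shape[2]:
        raise ValueError(
            f"kernel channel count {K.shape[2] if K.ndim == 4 else '?'} does not "
            f"match input channels {X.shape[2]}"
        )
    a, b, C, F = K.shape
    Sx, Sy = stride
    Ho = conv_output_shape(X.shape[0], a, padding, Sx)
    Wo = conv_output_shape(X.shape[1], b, padding, Sy)
    Xp = np.pad(X, ((padding, padding), (padding, padding), (0, 0)))
    Y = np.zeros((Ho, Wo, F))
    for f in range(F):
        for i in range(Ho):
            for j in range(Wo):
                acc = 0.0
                for c in range(C):
                    for p in range(a):
                        for q in range(b):
                            acc += K[p, q, c, f] * Xp[i * Sx + p, j * Sy + q, c]
                Y[i, j, f] = acc
    return Y[..., 0] if single else Y


def maxpool(Y: np.ndarray, k: int) -> np.ndarray:
    """Non-overlapping k x k max-pooling; trailing remainder rows/cols dropped."""
    if k < 1:
        raise ValueError("pooling size must be >= 1")
    Y = np.asarray(Y, dtype=float)
    Ho, Wo = Y.shape[0] // k, Y.shape[1] // k
    out = np.empty((Ho, Wo) + Y.shape[2:])
    for i in range(Ho):
        for j in range(Wo):
            out[i, j] = Y[i * k : (i + 1) * k, j * k : (j + 1) * k].max(axis=(0, 1))
    return out


def flatten_concat(feature_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Row-major flatten of each map, concatenated in input order."""
    if not feature_maps:
        return np.zeros(0)
    return np.concatenate([np.asarray(m, dtype=float).ravel() for m in feature_maps])


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def identity(x: np.ndarray) -> np.ndarray:
    return x


_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "relu": relu,
    "identity": identity,
    "linear": identity,
}


def dense_forward(
    h_prev: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    activation: str | Callable[[np.ndarray], np.ndarray] = "identity",
) -> np.ndarray:
    """One fully connected layer: sigma(W . h + b), with W of shape (s_out, s_in)."""
    W = np.asarray(weights, dtype=float)
    h = np.asarray(h_prev, dtype=float)
    b = np.asarray(bias, dtype=float)
    if W.ndim != 2 or W.shape[1] != h.shape[-1] or W.shape[0] != b.shape[-1]:
        raise ValueError(
            f"inconsistent dense shapes: W {W.shape}, h {h.shape}, b {b.shape}"
        )
    act = _ACTIVATIONS[activation] if isinstance(activation, str) else activation
    return act(h @ W.T + b)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: exp(x - max) / sum(exp(x - max))."""
    x = np.asarray(logits, dtype=float)
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolutional layer: N_f filters of shape (a, b)."""

    n_filters: int
    filter_shape: tuple[int, int] = (2, 2)
    strides: tuple[int, int] = (1, 1)
    padding: str = "same"  # "same" or "valid"
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.n_filters < 1 or min(self.filter_shape) < 1 or min(self.strides) < 1:
            raise ValueError("filter count, shape and strides must all be >= 1")
        if self.padding not in ("same", "valid"):
            raise ValueError(f"unknown padding mode {self.padding!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the classifier; defaults are the package's standard net."""

    input_shape: tuple[int, int, int] = (40, 40, 3)
    conv_layers: tuple[ConvLayerSpec, ...] = (
        ConvLayerSpec(n_filters=2),
        ConvLayerSpec(n_filters=4),
    )
    pool_sizes: tuple[int, ...] = (2, 2)
    dense_sizes: tuple[int, ...] = (48, 24)
    dropout_rate: float = 0.5
    n_classes: int = 6

    def __post_init__(self) -> None:
        if len(self.pool_sizes) != len(self.conv_layers):
            raise ValueError("need one pooling size per convolutional layer")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings: sparse categorical cross-entropy with Adam."""

    epochs: int = 100
    batch_size: int = 5
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# Fast batched layers (training path)
# ---------------------------------------------------------------------------


def _conv_forward(
    X: np.ndarray, K: np.ndarray, b: np.ndarray, pad: tuple[int, int, int, int],
    strides: tuple[int, int] = (1, 1),
) -> tuple[np.ndarray, np.ndarray]:
    """Batched strided cross-correlation. X (N,H,W,C), K (a,bk,C,F) -> (N,Ho,Wo,F).

    Implemented as a sum of shifted channel-matmuls (one per kernel tap), which
    is exact and avoids materializing an im2col buffer.  Returns (Y, Xp) with
    Xp the padded input cached for the backward pass.
    """
    a, bk, _, F = K.shape
    Sx, Sy = strides
    pt, pb, pl, pr = pad
    Xp = np.pad(X, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    Ho = (Xp.shape[1] - a) // Sx + 1
    Wo = (Xp.shape[2] - bk) // Sy + 1
    Y = np.zeros((X.shape[0], Ho, Wo, F), dtype=np.result_type(X.dtype, K.dtype))
    for p in range(a):
        for q in range(bk):
            patch = Xp[:, p : p + Sx * (Ho - 1) + 1 : Sx, q : q + Sy * (Wo - 1) + 1 : Sy, :]
            Y += patch @ K[p, q]
    return Y + b, Xp


def _conv_backward(
    dY: np.ndarray, Xp: np.ndarray, K: np.ndarray,
    pad: tuple[int, int, int, int], strides: tuple[int, int],
    input_shape: tuple[int, ...],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, bk, C, F = K.shape
    Sx, Sy = strides
    pt, pb, pl, pr = pad
    N, Ho, Wo, _ = dY.shape
    dK = np.zeros_like(K)
    dXp = np.zeros_like(Xp)
    dY_flat = dY.reshape(-1, F)
    for p in range(a):
        for q in range(bk):
            sl = np.s_[:, p : p + Sx * (Ho - 1) + 1 : Sx, q : q + Sy * (Wo - 1) + 1 : Sy, :]
            dK[p, q] = Xp[sl].reshape(-1, C).T @ dY_flat
            dXp[sl] += dY @ K[p, q].T
    db = dY.sum(axis=(0, 1, 2))
    H, W = input_shape[1], input_shape[2]
    dX = dXp[:, pt : pt + H, pl : pl + W, :]
    return dX, dK, db


def _pool_forward(X: np.ndarray, k: int) -> tuple[np.ndarray, tuple]:
    N, H, W, C = X.shape
    Ho, Wo = H // k, W // k
    Xc = (
        X[:, : Ho * k, : Wo * k, :]
        .reshape(N, Ho, k, Wo, k, C)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(N, Ho, Wo, C, k * k)
    )
    idx = Xc.argmax(axis=-1)
    Y = np.take_along_axis(Xc, idx[..., None], axis=-1)[..., 0]
    return Y, (idx, X.shape, k)


def _pool_backward(dY: np.ndarray, cache: tuple) -> np.ndarray:
    idx, in_shape, k = cache
    N, Ho, Wo, C = dY.shape
    dXc = np.zeros((N, Ho, Wo, C, k * k), dtype=dY.dtype)
    np.put_along_axis(dXc, idx[..., None], dY[..., None], axis=-1)
    dX = np.zeros(in_shape, dtype=dY.dtype)
    dX[:, : Ho * k, : Wo * k, :] = (
        dXc.reshape(N, Ho, Wo, C, k, k)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(N, Ho * k, Wo * k, C)
    )
    return dX


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


@dataclass
class TrainingHistory:
    """Per-epoch training loss and accuracy."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


class DCNN:
    """Convolution/pooling feature extractor with a dense softmax head.

    Construct with :func:`build_model`; parameters are created by
    :meth:`initialize` (or implicitly by :func:`train`).  ``class_names``
    fixes the meaning of the integer class indices.
    """

    def __init__(self, config: ModelConfig, class_names: Sequence[str] | None = None):
        self.config = config
        if class_names is not None and len(class_names) != config.n_classes:
            raise ValueError("class_names length must equal n_classes")
        self.class_names = tuple(class_names) if class_names is not None else None
        self.params: dict[str, np.ndarray] | None = None
        self.history: TrainingHistory | None = None
        self.layer_shapes = self._infer_shapes()

    # -- shape algebra ----------------------------------------------------
    def _infer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Every layer's output shape, from the convolution/pooling arithmetic."""
        cfg = self.config
        H, W, C = cfg.input_shape
        shapes: list[tuple[str, tuple[int, ...]]] = [("input", (H, W, C))]
        for i, (conv, k) in enumerate(zip(cfg.conv_layers, cfg.pool_sizes)):
            a, b = conv.filter_shape
            if conv.padding == "same":
                ph, pw = a - 1, b - 1  # total padding preserving size at stride 1
            else:
                ph = pw = 0
            # conv_output_shape takes symmetric P; fold total padding directly
            H = (H - a + ph) // conv.strides[0] + 1
            W = (W - b + pw) // conv.strides[1] + 1
            if H < 1 or W < 1:
                raise ValueError(f"conv layer {i}: output collapses to zero size")
            shapes.append((f"conv{i}", (H, W, conv.n_filters)))
            H, W = H // k, W // k
            if H < 1 or W < 1:
                raise ValueError(f"pool layer {i}: output collapses to zero size")
            shapes.append((f"pool{i}", (H, W, conv.n_filters)))
            C = conv.n_filters
        flat = H * W * C
        shapes.append(("flatten", (flat,)))
        s_prev = flat
        for i, s in enumerate(cfg.dense_sizes):
            shapes.append((f"dense{i}", (s,)))
            s_prev = s
        shapes.append(("output", (cfg.n_classes,)))
        return shapes

    @property
    def flat_size(self) -> int:
        return next(s[0] for name, s in self.layer_shapes if name == "flatten")

    # -- parameters -------------------------------------------------------
    def initialize(self, seed: int) -> None:
        """Glorot-uniform weights, zero biases; deterministic in ``seed``."""
        rng = np.random.default_rng(seed)
        cfg = self.config
        params: dict[str, np.ndarray] = {}

        def glorot(shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape).astype(np.float32)

        C = cfg.input_shape[2]
        for i, conv in enumerate(cfg.conv_layers):
            a, b = conv.filter_shape
            params[f"K{i}"] = glorot((a, b, C, conv.n_filters), a * b * C, a * b * conv.n_filters)
            params[f"bc{i}"] = np.zeros(conv.n_filters, dtype=np.float32)
            C = conv.n_filters
        s_prev = self.flat_size
        for i, s in enumerate(cfg.dense_sizes):
            params[f"W{i}"] = glorot((s, s_prev), s_prev, s)
            params[f"bd{i}"] = np.zeros(s, dtype=np.float32)
            s_prev = s
        params["Wout"] = glorot((cfg.n_classes, s_prev), s_prev, cfg.n_classes)
        params["bout"] = np.zeros(cfg.n_classes, dtype=np.float32)
        self.params = params

    # -- forward / backward ----------------------------------------------
    def _check_images(self, images: np.ndarray) -> np.ndarray:
        X = np.asarray(images)
        if X.dtype not in (np.float32, np.float64):
            X = X.astype(np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[1:] != self.config.input_shape:
            raise ValueError(
                f"images of shape {X.shape[1:]} do not match the model input "
                f"shape {self.config.input_shape}"
            )
        return X

    def forward(
        self,
        images: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Batched forward pass to logits; dropout only when ``training``."""
        if self.params is None:
            raise RuntimeError("model has no parameters; call initialize() or train()")
        cfg = self.config
        X = self._check_images(images)
        if training and cfg.dropout_rate > 0 and rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")
        cache: dict = {"X": X}
        A = X
        for i, (conv, k) in enumerate(zip(cfg.conv_layers, cfg.pool_sizes)):
            a, b = conv.filter_shape
            if conv.padding == "same":
                pt, pb = same_padding(a)
                pl, pr = same_padding(b)
            else:
                pt = pb = pl = pr = 0
            Z, Xp = _conv_forward(
                A, self.params[f"K{i}"], self.params[f"bc{i}"], (pt, pb, pl, pr), conv.strides
            )
            R = relu(Z)
            P, pool_cache = _pool_forward(R, k)
            cache[f"conv{i}"] = (Xp, Z, (pt, pb, pl, pr), conv.strides, A.shape)
            cache[f"pool{i}"] = pool_cache
            A = P
        flat = A.reshape(A.shape[0], -1)
        cache["flat_shape"] = A.shape
        h = flat
        for i in range(len(cfg.dense_sizes)):
            Zd = h @ self.params[f"W{i}"].T + self.params[f"bd{i}"]
            Ad = relu(Zd)
            if training and cfg.dropout_rate > 0:
                mask = (rng.random(Ad.shape) >= cfg.dropout_rate).astype(Ad.dtype)
                mask /= 1.0 - cfg.dropout_rate
                Ad = Ad * mask
            else:
                mask = None
            cache[f"dense{i}"] = (h, Zd, mask)
            h = Ad
        logits = h @ self.params["Wout"].T + self.params["bout"]
        cache["out_in"] = h
        return (logits, cache) if return_cache else logits

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        N = len(y)
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N
        grads["Wout"] = dlogits.T @ cache["out_in"]
        grads["bout"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["Wout"]
        for i in reversed(range(len(cfg.dense_sizes))):
            h_in, Zd, mask = cache[f"dense{i}"]
            if mask is not None:
                dh = dh * mask
            dZ = dh * (Zd > 0)
            grads[f"W{i}"] = dZ.T @ h_in
            grads[f"bd{i}"] = dZ.sum(axis=0)
            dh = dZ @ self.params[f"W{i}"]
        dA = dh.reshape(cache["flat_shape"])
        for i in reversed(range(len(cfg.conv_layers))):
            dR = _pool_backward(dA, cache[f"pool{i}"])
            Xp, Z, pad, strides, in_shape = cache[f"conv{i}"]
            dZ = dR * (Z > 0)
            dA, dK, db = _conv_backward(dZ, Xp, self.params[f"K{i}"], pad, strides, in_shape)
            grads[f"K{i}"] = dK
            grads[f"bc{i}"] = db
        return grads


def build_model(config: ModelConfig, class_names: Sequence[str] | None = None) -> DCNN:
    """Construct an untrained model, validating the whole shape algebra."""
    return DCNN(config, class_names)


def sparse_categorical_cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels under softmax(logits)."""
    probs = softmax(logits)
    n = len(y)
    eps = np.finfo(float).tiny
    return float(-np.log(probs[np.arange(n), y] + eps).mean())


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], tc: TrainingConfig):
        self.tc = tc
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        tc = self.tc
        self.t += 1
        bias1 = 1 - tc.beta1**self.t
        bias2 = 1 - tc.beta2**self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype)
            self.m[k] = tc.beta1 * self.m[k] + (1 - tc.beta1) * g
            self.v[k] = tc.beta2 * self.v[k] + (1 - tc.beta2) * g * g
            m_hat = self.m[k] / bias1
            v_hat = self.v[k] / bias2
            params[k] -= tc.learning_rate * m_hat / (np.sqrt(v_hat) + tc.epsilon)


def train(
    model: DCNN,
    images: np.ndarray,
    labels: np.ndarray,
    tc: TrainingConfig,
) -> DCNN:
    """Train in place with mini-batch Adam on sparse cross-entropy.

    Labels are integer class indices in ``[0, n_classes)``.  All randomness
    (weight init, shuffling, dropout) flows from ``tc.seed``, so the result
    is deterministic for a fixed seed and thread-free numpy backend.
    Returns the model with a populated :class:`TrainingHistory`.
    """
    X = model._check_images(images)
    y = np.asarray(labels)
    if len(X) == 0:
        raise ValueError("cannot train on an empty dataset")
    if len(X) != len(y):
        raise ValueError("images and labels differ in length")
    if not np.issubdtype(y.dtype, np.integer):
        raise ValueError("labels must be integer class indices (sparse encoding)")
    if y.min() < 0 or y.max() >= model.config.n_classes:
        raise ValueError(
            f"labels must lie in [0, {model.config.n_classes}), "
            f"got range [{y.min()}, {y.max()}]"
        )
    rng = np.random.default_rng(tc.seed)
    model.initialize(int(rng.integers(2**31)))
    optimizer = _Adam(model.params, tc)
    history = TrainingHistory()
    n = len(X)
    for _ in range(tc.epochs):
        order = rng.permutation(n) if tc.shuffle else np.arange(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            logits, cache = model.forward(X[idx], training=True, rng=rng, return_cache=True)
            probs = softmax(logits)
            eps = np.finfo(float).tiny
            batch_loss = -np.log(probs[np.arange(len(idx)), y[idx]] + eps).sum()
            epoch_loss += float(batch_loss)
            epoch_correct += int((probs.argmax(axis=1) == y[idx]).sum())
            grads = model._backward(probs, y[idx], cache)
            optimizer.step(model.params, grads)
        history.loss.append(epoch_loss / n)
        history.accuracy.append(epoch_correct / n)
    model.history = history
    return model


def predict(model: DCNN, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices and softmax probabilities for a batch of images.

    The predicted class is the argmax of the probability vector; exact ties
    resolve to the lowest class index.
    """
    logits = model.forward(images, training=False)
    probs = softmax(logits)
    return probs.argmax(axis=1), probs


def save_model(model: DCNN, path: str) -> None:
    """Serialize config, class names and parameters to an .npz checkpoint."""
    import json

    if model.params is None:
        raise ValueError("model has no parameters to save")
    meta = {
        "input_shape": list(model.config.input_shape),
        "conv_layers": [
            {
                "n_filters": c.n_filters,
                "filter_shape": list(c.filter_shape),
                "strides": list(c.strides),
                "padding": c.padding,
                "activation": c.activation,
            }
            for c in model.config.conv_layers
        ],
        "pool_sizes": list(model.config.pool_sizes),
        "dense_sizes": list(model.config.dense_sizes),
        "dropout_rate": model.config.dropout_rate,
        "n_classes": model.config.n_classes,
        "class_names": list(model.class_names) if model.class_names else None,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_model(path: str) -> DCNN:
    """Load a checkpoint written by :func:`save_model`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(
            input_shape=tuple(meta["input_shape"]),
            conv_layers=tuple(
                ConvLayerSpec(
                    n_filters=c["n_filters"],
                    filter_shape=tuple(c["filter_shape"]),
                    strides=tuple(c["strides"]),
                    padding=c["padding"],
                    activation=c["activation"],
                )
                for c in meta["conv_layers"]
            ),
            pool_sizes=tuple(meta["pool_sizes"]),
            dense_sizes=tuple(meta["dense_sizes"]),
            dropout_rate=meta["dropout_rate"],
            n_classes=meta["n_classes"],
        )
        model = DCNN(config, meta["class_names"])
        model.params = {k: data[k] for k in data.files if k != "__meta__"}
    return model
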
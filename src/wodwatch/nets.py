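"""Convolutional network for window classification, implemented on numpy.

The same base architecture serves both tasks: exercise recognition (11-way
softmax including the null class) and per-exercise repetition-start detection
(binary softmax).  A window of W samples x (3*S) channels is treated as a 2-D
array whose vertical axis stacks the sensors; the first convolution uses a
vertical kernel extent of 3 with vertical stride 3, so the three axes of one
sensor are combined but axes of different sensors are never mixed.  Deeper
layers convolve along time only, per sensor column.  Two dense layers with a
softmax output complete the model.

Convolutions are evaluated as a sum of shifted tensordots (one BLAS matmul
per kernel offset), with hand-written backpropagation; training is plain SGD
(optional momentum) on the cross-entropy loss with inverted dropout and
early stopping on validation loss.  Everything is float32 and fully
deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .types import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters.

    Defaults are the best recognition values of the grid search: 5
    convolutional layers with 100/75/25/25/75 filters, first kernel (15, 3)
    with vertical stride 3, dropout 0.5 on every layer, two dense layers.
    The vertical kernel extent must be non-overlapping (equal to the vertical
    stride) and divide the channel count; 3 keeps sensor triplets separate,
    while larger extents (6, 18) mix whole sensors as in the wider grid
    candidates.
    """

    n_conv_layers: int = 5
    filters: tuple[int, ...] = (100, 75, 25, 25, 75)
    first_kernel: tuple[int, int] = (15, 3)
    first_vertical_stride: int = 3
    first_time_stride: int = 1  # temporal stride of layer 1
    kernel_time: int = 15  # temporal extent of layers 2..n
    conv_time_stride: int = 1  # temporal stride of layers 2..n
    dense_units: tuple[int, ...] = (128,)
    dropout: float = 0.5
    activation: str = "relu"

    def __post_init__(self) -> None:
        if len(self.filters) != self.n_conv_layers:
            raise ValidationError(
                f"{len(self.filters)} filter sizes for "
                f"{self.n_conv_layers} conv layers"
            )
        if self.first_kernel[1] != self.first_vertical_stride:
            raise ValidationError(
                "first-layer vertical kernel extent must equal the vertical "
                "stride (non-overlapping sensor groups)"
            )
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")
        if self.activation not in ("relu", "elu"):
            raise ValidationError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters (defaults: SGD, lr 1e-4, batch 30,
    at most 100 epochs with early stopping on validation loss)."""

    batch_size: int = 30
    learning_rate: float = 1e-4
    momentum: float = 0.0
    max_epochs: int = 100
    early_stopping_patience: int = 10
    rng_seed: int = 0
    normalize_input: bool = True
    steps_per_epoch: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be positive")
        if self.early_stopping_patience < 1:
            raise ValidationError("patience must be >= 1")


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    return np.where(x > 0, x, np.expm1(x))  # elu


def _act_grad(x: np.ndarray, out: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (x > 0).astype(x.dtype)
    return np.where(x > 0, 1.0, out + 1.0).astype(x.dtype)


def _conv_out_len(T: int, k: int, stride: int) -> int:
    return (T - k) // stride + 1


class ConvNet:
    """A trained or untrained window classifier.  Build via :func:`build_model`."""

    def __init__(self, spec: ModelSpec, input_shape: tuple[int, int], n_classes: int):
        W, C = input_shape
        kt, kv = spec.first_kernel
        if C % 3 != 0:
            raise ValidationError(f"channel count {C} not divisible by 3")
        if C % kv != 0:
            raise ValidationError(
                f"vertical kernel extent {kv} does not divide channel count {C}"
            )
        self.spec = spec
        self.input_shape = (W, C)
        self.n_classes = n_classes
        self.n_columns = C // kv
        # per-layer (temporal kernel, temporal stride, fan-in, fan-out)
        self._conv_shapes: list[tuple[int, int, int, int]] = []
        T, fan_in = W, kv
        for i, f in enumerate(spec.filters):
            k = kt if i == 0 else spec.kernel_time
            st = spec.first_time_stride if i == 0 else spec.conv_time_stride
            T_out = _conv_out_len(T, k, st)
            if T_out < 1:
                raise ValidationError(
                    f"window of {W} samples too short for conv layer {i + 1}"
                )
            self._conv_shapes.append((k, st, fan_in, f))
            T, fan_in = T_out, f
        self._flat_dim = T * self.n_columns * fan_in
        self._dense_shapes = []
        d_in = self._flat_dim
        for u in spec.dense_units:
            self._dense_shapes.append((d_in, u))
            d_in = u
        self._dense_shapes.append((d_in, n_classes))
        self.params: list[dict[str, np.ndarray]] = []
        self.norm_mean: Optional[np.ndarray] = None
        self.norm_std: Optional[np.ndarray] = None
        self._velocity: Optional[list[dict[str, np.ndarray]]] = None

    # ---------------------------------------------------------------- setup
    def initialize(self, rng: np.random.Generator) -> "ConvNet":
        """He-normal weight initialization (deterministic given the rng)."""
        self.params = []
        for k, _st, f_in, f_out in self._conv_shapes:
            fan = k * f_in
            self.params.append(
                {
                    "W": rng.normal(0, np.sqrt(2.0 / fan), (k, f_in, f_out)).astype(
                        np.float32
                    ),
                    "b": np.zeros(f_out, dtype=np.float32),
                }
            )
        for d_in, d_out in self._dense_shapes:
            self.params.append(
                {
                    "W": rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(
                        np.float32
                    ),
                    "b": np.zeros(d_out, dtype=np.float32),
                }
            )
        self._velocity = None
        return self

    @property
    def n_parameters(self) -> int:
        return int(sum(p["W"].size + p["b"].size for p in self.params))

    # ------------------------------------------------------------- plumbing
    def _normalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if self.norm_mean is not None:
            x = (x - self.norm_mean) / self.norm_std
        return x

    @staticmethod
    def _im2col(x, k, stride):
        """Patches (B, T_out, S, k*F) of a (B, T, S, F) input."""
        v = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # B,T',S,F,k
        v = v[:, ::stride].transpose(0, 1, 2, 4, 3)  # B,T_out,S,k,F
        B, T_out, S = v.shape[:3]
        return np.ascontiguousarray(v).reshape(B, T_out, S, -1)

    @classmethod
    def _conv_forward(cls, x, W, b, stride, cache=None):
        k, f_in, f_out = W.shape
        cols = cls._im2col(x, k, stride)
        if cache is not None:
            cache.append(cols)
        out = cols.reshape(-1, k * f_in) @ W.reshape(k * f_in, f_out) + b
        return out.reshape(*cols.shape[:3], f_out)

    @staticmethod
    def _conv_backward(x, cols, W, stride, dout):
        k, f_in, f_out = W.shape
        B, T_out, S = dout.shape[:3]
        d2 = dout.reshape(-1, f_out)
        dW = (cols.reshape(-1, k * f_in).T @ d2).reshape(W.shape)
        db = d2.sum(axis=0)
        dcols = (d2 @ W.reshape(k * f_in, f_out).T).reshape(B, T_out, S, k, f_in)
        dx = np.zeros_like(x)
        end = stride * (T_out - 1) + 1
        for o in range(k):
            dx[:, o : o + end : stride] += dcols[:, :, :, o, :]
        return dx, dW, db

    def _forward(self, x, train=False, rng=None):
        """Returns class probabilities and, in training mode, a cache."""
        act = self.spec.activation
        drop = self.spec.dropout if train else 0.0
        B = x.shape[0]
        h = x.reshape(B, x.shape[1], self.n_columns, -1)
        cache = {"inputs": [], "pre": [], "post": [], "masks": [], "cols": []}
        for i, (_k, st, _fi, _fo) in enumerate(self._conv_shapes):
            p = self.params[i]
            cache["inputs"].append(h)
            z = self._conv_forward(
                h, p["W"], p["b"], st, cache["cols"] if train else None
            )
            a = _act(z, act)
            cache["pre"].append(z)
            cache["post"].append(a)
            mask = None
            if drop > 0:
                mask = (rng.random(a.shape) >= drop).astype(a.dtype) / (1 - drop)
                a = a * mask
            cache["masks"].append(mask)
            h = a
        h = h.reshape(B, -1)
        n_conv = len(self._conv_shapes)
        for j in range(len(self._dense_shapes) - 1):
            p = self.params[n_conv + j]
            cache["inputs"].append(h)
            z = h @ p["W"] + p["b"]
            a = _act(z, act)
            cache["pre"].append(z)
            cache["post"].append(a)
            mask = None
            if drop > 0:
                mask = (rng.random(a.shape) >= drop).astype(a.dtype) / (1 - drop)
                a = a * mask
            cache["masks"].append(mask)
            h = a
        p = self.params[-1]
        cache["inputs"].append(h)
        logits = h @ p["W"] + p["b"]
        logits = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        probs = ex / ex.sum(axis=1, keepdims=True)
        return probs, cache

    def _backward(self, probs, y, cache):
        """Gradients of mean cross-entropy w.r.t. all parameters."""
        act = self.spec.activation
        B = probs.shape[0]
        grads = [None] * len(self.params)
        d = probs.copy()
        d[np.arange(B), y] -= 1.0
        d /= B
        n_conv = len(self._conv_shapes)
        n_dense = len(self._dense_shapes)
        # output layer
        h = cache["inputs"][-1]
        grads[-1] = {"W": h.T @ d, "b": d.sum(axis=0)}
        d = d @ self.params[-1]["W"].T
        # hidden dense layers
        for j in range(n_dense - 2, -1, -1):
            li = n_conv + j
            mask = cache["masks"][li]
            if mask is not None:
                d = d * mask
            d = d * _act_grad(cache["pre"][li], cache["post"][li], act)
            h = cache["inputs"][li]
            grads[li] = {"W": h.T @ d, "b": d.sum(axis=0)}
            d = d @ self.params[li]["W"].T
        # reshape into the last conv output
        last = cache["pre"][n_conv - 1]
        d = d.reshape(last.shape)
        for i in range(n_conv - 1, -1, -1):
            mask = cache["masks"][i]
            if mask is not None:
                d = d * mask
            d = d * _act_grad(cache["pre"][i], cache["post"][i], act)
            x = cache["inputs"][i]
            _k, st, _fi, _fo = self._conv_shapes[i]
            d, dW, db = self._conv_backward(
                x, cache["cols"][i], self.params[i]["W"], st, d
            )
            grads[i] = {"W": dW, "b": db}
        return grads

    def _sgd_step(self, grads, lr, momentum):
        if self._velocity is None:
            self._velocity = [
                {k: np.zeros_like(v) for k, v in p.items()} for p in self.params
            ]
        for p, g, v in zip(self.params, grads, self._velocity):
            for k in p:
                v[k] = momentum * v[k] - lr * g[k].astype(p[k].dtype)
                p[k] += v[k]

    # ---------------------------------------------------------------- API
    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Class probabilities for an array of windows (n, W, C)."""
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != self.input_shape:
            raise ValidationError(
                f"window shape {X.shape[1:]} does not match model input "
                f"{self.input_shape}"
            )
        out = np.empty((X.shape[0], self.n_classes), dtype=np.float32)
        for i in range(0, X.shape[0], batch):
            xb = self._normalize(X[i : i + batch])
            out[i : i + batch], _ = self._forward(xb, train=False)
        return out

    # -------------------------------------------------------------- saving
    def save(self, path) -> None:
        meta = {
            "spec": asdict(self.spec),
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "normalized": self.norm_mean is not None,
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for i, p in enumerate(self.params):
            arrays[f"W{i}"] = p["W"]
            arrays[f"b{i}"] = p["b"]
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_std"] = self.norm_std
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ConvNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec_d = meta["spec"]
            for key in ("filters", "first_kernel", "dense_units"):
                spec_d[key] = tuple(spec_d[key])
            model = cls(
                ModelSpec(**spec_d), tuple(meta["input_shape"]), meta["n_classes"]
            )
            model.params = []
            i = 0
            while f"W{i}" in data:
                model.params.append({"W": data[f"W{i}"], "b": data[f"b{i}"]})
                i += 1
            if meta["normalized"]:
                model.norm_mean = data["norm_mean"]
                model.norm_std = data["norm_std"]
        return model


def build_model(
    spec: ModelSpec, input_shape: tuple[int, int], n_classes: int, seed: int = 0
) -> ConvNet:
    """Construct and initialize an untrained model.

    ``input_shape`` is (window samples, channels); channels must be divisible
    by 3 (each sensor contributes its three axes).
    """
    rng = np.random.default_rng(seed)
    return ConvNet(spec, tuple(input_shape), n_classes).initialize(rng)


def train(
    model: ConvNet,
    train_pool: tuple[np.ndarray, np.ndarray],
    val_pool: Optional[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[ConvNet, dict]:
    """SGD training with uniform batch resampling and early stopping.

    Batches are drawn independently and uniformly at random (with
    replacement) from the training pool.  After each epoch the validation
    loss is evaluated; training stops when it has not improved for
    ``early_stopping_patience`` epochs, and the best-validation weights are
    restored.  Fully deterministic given ``cfg.rng_seed``.
    """
    X, y = train_pool
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValidationError("empty training pool")
    if y.max(initial=0) >= model.n_classes:
        raise ValidationError("label outside the model's class range")
    rng = np.random.default_rng(cfg.rng_seed)
    if cfg.normalize_input:
        model.norm_mean = X.mean(axis=(0, 1), dtype=np.float64).astype(np.float32)
        sd = X.std(axis=(0, 1), dtype=np.float64).astype(np.float32)
        model.norm_std = np.where(sd > 1e-6, sd, 1.0).astype(np.float32)
    Xn = model._normalize(X)
    if val_pool is not None:
        Xv = np.asarray(val_pool[0], dtype=np.float32)
        yv = np.asarray(val_pool[1], dtype=np.int64)
    else:
        Xv, yv = X, y
    n = X.shape[0]
    steps = cfg.steps_per_epoch or max(1, int(np.ceil(n / cfg.batch_size)))
    history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best_loss, best_params, patience_left = np.inf, None, cfg.early_stopping_patience
    for epoch in range(cfg.max_epochs):
        losses = []
        for _ in range(steps):
            idx = rng.integers(0, n, size=cfg.batch_size)
            xb, yb = Xn[idx], y[idx]
            probs, cache = model._forward(xb, train=True, rng=rng)
            loss = float(
                -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            losses.append(loss)
            grads = model._backward(probs, yb, cache)
            model._sgd_step(grads, cfg.learning_rate, cfg.momentum)
        pv = model.predict_proba(Xv)
        val_loss = float(-np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12)))
        val_acc = float(np.mean(pv.argmax(axis=1) == yv))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = [{k: v.copy() for k, v in p.items()} for p in model.params]
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_params is not None:
        model.params = best_params
    return model, history


def predict_windows(model: ConvNet, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probability vectors and argmax labels for an array of windows.

    Ties in the argmax go to the lowest class index (numpy argmax semantics).
    """
    probs = model.predict_proba(windows)
    return probs, probs.argmax(axis=1)
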
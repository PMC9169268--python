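"""CNN regression model for kernel and shell weight, implemented in NumPy.

The network is AlexNet-like: five valid-padded convolutions (96@11x11 stride 4,
256@5x5, 384@3x3, 384@3x3, 256@3x3) with 3x3/stride-2 max-pools after the first
and second convolutions, two 200-unit fully connected layers with 50% dropout,
and a two-neuron linear output predicting kernel and shell weight in grams.
Training minimizes a sample-weighted MSE with Adam (lr 5e-5, beta1 0.9,
beta2 0.999, eps 1e-8), batches of 50, Glorot-uniform weights and zero biases.
Sample weights are inversely proportional to the frequency of a pod's target
weights in the training distribution, countering the right skew of the data.

Layers use im2col/col2im convolutions on float32 arrays (NCHW); with a fixed
seed and single-threaded BLAS, training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CNNSpec",
    "SampleWeights",
    "TrainedModel",
    "Network",
    "default_spec",
    "desk_spec",
    "build_network",
    "compute_sample_weights",
    "weighted_mse",
    "train",
    "predict_weights_cnn",
    "images_to_input",
]


# --------------------------------------------------------------------------- spec


@dataclass(frozen=True)
class CNNSpec:
    """Architecture and training recipe.

    ``conv_layers`` are (filters, kernel, stride) with valid padding and ReLU;
    ``pool_after`` lists the (0-based) conv indices followed by a max-pool of
    ``pool_size``/``pool_stride``.  ``fc_layers`` are the hidden widths, each of
    the first ``n_dropout_fc`` followed by dropout at ``dropout_rate``.  The
    output layer is linear with ``n_outputs`` neurons.
    """

    input_size: int = 227
    conv_layers: tuple[tuple[int, int, int], ...] = (
        (96, 11, 4),
        (256, 5, 1),
        (384, 3, 1),
        (384, 3, 1),
        (256, 3, 1),
    )
    pool_after: tuple[int, ...] = (0, 1)
    pool_size: int = 3
    pool_stride: int = 2
    fc_layers: tuple[int, ...] = (200, 200)
    n_dropout_fc: int = 2
    dropout_rate: float = 0.5
    n_outputs: int = 2
    learning_rate: float = 5e-5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 50
    epochs: int = 30
    rng_seed: int = 0


def default_spec(**overrides) -> CNNSpec:
    """The reference architecture and recipe."""
    return replace(CNNSpec(), **overrides) if overrides else CNNSpec()


def desk_spec(seed: int = 0, **overrides) -> CNNSpec:
    """A width-reduced variant for single-CPU experiments.

    Layer inventory (five convs with the same kernels/strides, two max-pools,
    two dropout-FC layers, two outputs) is unchanged; filter counts and FC
    widths are cut and the input shrunk to 163 px, the smallest size the
    valid-padded stack admits.
    """
    kw = dict(
        input_size=163,
        conv_layers=((24, 11, 4), (64, 5, 1), (96, 3, 1), (96, 3, 1), (64, 3, 1)),
        fc_layers=(100, 100),
        rng_seed=seed,
    )
    kw.update(overrides)
    return CNNSpec(**kw)


# --------------------------------------------------------------------------- layers


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int, s: int) -> np.ndarray:
    """(N, C, H, W) -> (N, OH*OW, C*k*k) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # N,C,OH,OW,k,k
    n, c, oh, ow, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k), oh, ow


def _col2im(cols: np.ndarray, x_shape, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back onto the image."""
    n, c, h, w = x_shape
    dx = np.zeros(x_shape, dtype=cols.dtype)
    g = cols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)  # N,C,OH,OW,k,k
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + oh * s : s, j : j + ow * s : s] += g[:, :, :, :, i, j]
    return dx


class Conv2D:
    def __init__(self, rng, c_in, filters, kernel, stride, relu=True):
        self.k, self.s, self.relu = kernel, stride, relu
        fan_in = c_in * kernel * kernel
        fan_out = filters * kernel * kernel
        self.W = _glorot_uniform(rng, (filters, fan_in), fan_in, fan_out)
        self.b = np.zeros(filters, dtype=np.float32)

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(x, self.k, self.s)
        out = cols @ self.W.T + self.b  # N, OH*OW, F
        out = out.transpose(0, 2, 1).reshape(x.shape[0], -1, oh, ow)
        self._cache = (x.shape, np.ascontiguousarray(cols), oh, ow)
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        x_shape, cols, oh, ow = self._cache
        if self.relu:
            dout = dout * self._mask
        n, f = dout.shape[0], dout.shape[1]
        d = dout.reshape(n, f, oh * ow).transpose(0, 2, 1)  # N, OH*OW, F
        self.dW = np.einsum("npf,npc->fc", d, cols, optimize=True)
        self.db = d.sum(axis=(0, 1))
        dcols = d @ self.W
        return _col2im(dcols, x_shape, self.k, self.s, oh, ow)

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]

    def describe(self):
        return {
            "type": "conv",
            "filters": self.W.shape[0],
            "kernel": self.k,
            "stride": self.s,
            "activation": "relu" if self.relu else "linear",
        }


class MaxPool:
    def __init__(self, size, stride):
        self.k, self.s = size, stride

    def forward(self, x, train=False):
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))[:, :, :: self.s, :: self.s]
        n, c, oh, ow, _, _ = win.shape
        flat = win.reshape(n, c, oh, ow, self.k * self.k)
        self._arg = flat.argmax(axis=-1)
        self._x_shape = x.shape
        self._ohw = (oh, ow)
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._x_shape
        oh, ow = self._ohw
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        ii, jj = np.divmod(self._arg, self.k)
        rows = (np.arange(oh) * self.s)[None, None, :, None] + ii
        colc = (np.arange(ow) * self.s)[None, None, None, :] + jj
        ns = np.arange(n)[:, None, None, None]
        cs = np.arange(c)[None, :, None, None]
        np.add.at(dx, (ns, cs, rows, colc), dout)
        return dx

    @property
    def params(self):
        return []

    def describe(self):
        return {"type": "maxpool", "size": self.k, "stride": self.s}


class Flatten:
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    @property
    def params(self):
        return []

    def describe(self):
        return {"type": "flatten"}


class Dense:
    def __init__(self, rng, n_in, n_out, relu=True):
        self.W = _glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.W + self.b
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]

    def describe(self):
        return {
            "type": "dense",
            "units": self.W.shape[1],
            "activation": "relu" if self.relu else "linear",
        }


class Dropout:
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate):
        self.rate = rate
        self.rng = np.random.default_rng(0)  # rebound by the trainer

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    @property
    def params(self):
        return []

    def describe(self):
        return {"type": "dropout", "rate": self.rate}


# --------------------------------------------------------------------------- network


class Network:
    """A plain sequential network with explicit forward/backward passes."""

    def __init__(self, layers, spec: CNNSpec):
        self.layers = layers
        self.spec = spec

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def describe(self) -> list[dict]:
        return [layer.describe() for layer in self.layers]

    def parameters(self):
        for layer in self.layers:
            for name, arr, gname in layer.params:
                yield layer, name, arr, gname

    def spatial_sizes(self) -> list[int]:
        """Per-stage spatial extents of the conv/pool stack (for auditing)."""
        n = self.spec.input_size
        sizes = []
        for i, (f, k, s) in enumerate(self.spec.conv_layers):
            n = (n - k) // s + 1
            sizes.append(n)
            if i in self.spec.pool_after:
                n = (n - self.spec.pool_size) // self.spec.pool_stride + 1
                sizes.append(n)
        return sizes


def build_network(spec: CNNSpec) -> Network:
    """Instantiate the network, validating that no layer's extent underflows."""
    rng = np.random.default_rng(spec.rng_seed)
    layers = []
    n, c = spec.input_size, 1
    for i, (f, k, s) in enumerate(spec.conv_layers):
        out = (n - k) // s + 1
        if n < k or out < 1:
            raise ValueError(
                f"conv{i + 1} ({f}@{k}x{k}/s{s}) underflows: input extent {n} < kernel {k}"
            )
        layers.append(Conv2D(rng, c, f, k, s))
        n, c = out, f
        if i in spec.pool_after:
            out = (n - spec.pool_size) // spec.pool_stride + 1
            if n < spec.pool_size or out < 1:
                raise ValueError(f"max-pool after conv{i + 1} underflows: extent {n}")
            layers.append(MaxPool(spec.pool_size, spec.pool_stride))
            n = out
    layers.append(Flatten())
    n_feat = c * n * n
    for j, width in enumerate(spec.fc_layers):
        layers.append(Dense(rng, n_feat, width, relu=True))
        if j < spec.n_dropout_fc:
            layers.append(Dropout(spec.dropout_rate))
        n_feat = width
    layers.append(Dense(rng, n_feat, spec.n_outputs, relu=False))
    return Network(layers, spec)


# --------------------------------------------------------------------------- weighting


@dataclass(frozen=True)
class SampleWeights:
    """Per-pod loss multipliers (mean 1) with the per-trait raw weights kept."""

    weights: np.ndarray
    per_trait: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise ValueError("sample weights must be positive")


def compute_sample_weights(targets: np.ndarray, n_bins: int = 20) -> SampleWeights:
    """Inverse-frequency sample weighting over the target distribution.

    Per trait, targets are histogrammed into ``n_bins`` equal-width bins over
    the observed range and each pod gets the reciprocal of its bin's count;
    the pod's combined weight is the mean of its two trait weights, normalized
    to mean 1.  Rare (extreme) weights thus contribute more to the loss.
    """
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    n, n_traits = t.shape
    if not 2 <= n_bins <= n:
        raise ValueError("need n >= n_bins >= 2")
    per_trait = np.ones((n, n_traits))
    for j in range(n_traits):
        col = t[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            continue  # degenerate: uniform weights for this trait
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.digitize(col, edges[1:-1]), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        per_trait[:, j] = 1.0 / counts[idx]
    combined = per_trait.mean(axis=1)
    combined = combined / combined.mean()
    return SampleWeights(weights=combined, per_trait=per_trait, n_bins=n_bins)


# --------------------------------------------------------------------------- training


def weighted_mse(pred: np.ndarray, target: np.ndarray, weights: np.ndarray) -> float:
    """mean_i( w_i * mean_j (pred_ij - target_ij)^2 ); plain MSE when w == 1."""
    per_sample = np.mean((pred - target) ** 2, axis=1)
    return float(np.mean(weights * per_sample))


class Adam:
    def __init__(self, net: Network, spec: CNNSpec):
        self.lr, self.b1, self.b2, self.eps = (
            spec.learning_rate,
            spec.beta1,
            spec.beta2,
            spec.eps,
        )
        self.t = 0
        self.state = {}
        for layer, name, arr, _ in net.parameters():
            self.state[(id(layer), name)] = (
                np.zeros_like(arr),
                np.zeros_like(arr),
            )

    def step(self, net: Network) -> None:
        self.t += 1
        for layer, name, arr, gname in net.parameters():
            g = getattr(layer, gname).astype(arr.dtype)
            m, v = self.state[(id(layer), name)]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    """A trained network plus its per-epoch history (loss and MAE curves)."""

    network: Network
    history: "object"  # pandas DataFrame: epoch, train_loss, train_mae, val_mae
    spec: CNNSpec
    seed: int


def train(
    network: Network,
    images: np.ndarray,
    targets: np.ndarray,
    sample_weights: SampleWeights | np.ndarray | None = None,
    val_images: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
    epochs: int | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train with sample-weighted MSE and Adam; record per-epoch history.

    ``images`` is (N, H, W) or (N, 1, H, W) float; targets (N, 2) grams.  The
    caller supplies the validation set (the 20% of the calibration data held
    out to monitor accuracy each epoch).  All randomness (shuffling, dropout)
    derives from the spec seed.
    """
    import pandas as pd

    spec = network.spec
    epochs = epochs if epochs is not None else spec.epochs
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    y = np.asarray(targets, dtype=np.float32)
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if sample_weights is None:
        w = np.ones(n, dtype=np.float32)
    elif isinstance(sample_weights, SampleWeights):
        w = sample_weights.weights.astype(np.float32)
    else:
        w = np.asarray(sample_weights, dtype=np.float32)

    rng = np.random.default_rng(spec.rng_seed + 1)
    for layer in network.layers:
        if isinstance(layer, Dropout):
            layer.rng = rng
    opt = Adam(network, spec)
    hist = []
    n_out = y.shape[1]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, maes, sizes = [], [], []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb, wb = x[idx], y[idx], w[idx]
            pred = network.forward(xb, train=True)
            loss = weighted_mse(pred, yb, wb)
            if not np.isfinite(loss):
                finite = pred[np.isfinite(pred)]
                rng_txt = (
                    f"[{finite.min()}, {finite.max()}]" if finite.size else "all non-finite"
                )
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1} (finite pred range {rng_txt})"
                )
            grad = (2.0 * wb[:, None] * (pred - yb) / (len(idx) * n_out)).astype(np.float32)
            network.backward(grad)
            opt.step(network)
            losses.append(loss)
            maes.append(float(np.mean(np.abs(pred - yb))))
            sizes.append(len(idx))
        sizes = np.asarray(sizes, dtype=float)
        train_loss = float(np.average(losses, weights=sizes))
        train_mae = float(np.average(maes, weights=sizes))
        if val_images is not None and len(val_images):
            val_pred = predict_weights_cnn(network, val_images, floor=False)
            val_mae = float(np.mean(np.abs(val_pred - np.asarray(val_targets))))
        else:
            val_mae = np.nan
        hist.append(
            {
                "epoch": epoch + 1,
                "train_loss": train_loss,
                "train_mae": train_mae,
                "val_mae": val_mae,
            }
        )
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: loss={train_loss:.4f} val_mae={val_mae:.4f}")
    return TrainedModel(
        network=network,
        history=pd.DataFrame(hist),
        spec=spec,
        seed=spec.rng_seed,
    )


def predict_weights_cnn(
    network: Network, images: np.ndarray, batch_size: int = 64, floor: bool = True
) -> np.ndarray:
    """Inference (dropout off): (N, 2) predicted (kernel_g, shell_g).

    Negative outputs are floored at 0 by default (masses cannot be negative).
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    outs = []
    for start in range(0, x.shape[0], batch_size):
        outs.append(network.forward(x[start : start + batch_size], train=False))
    pred = np.concatenate(outs, axis=0).astype(float)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("non-finite predictions")
    return np.clip(pred, 0.0, None) if floor else pred


# --------------------------------------------------------------------------- input prep


def images_to_input(images: list[np.ndarray], input_size: int) -> np.ndarray:
    """Zero-pad each image to a square (preserving aspect) and resize.

    Returns (N, input_size, input_size) float32, the network's input tensor.
    """
    from skimage.transform import resize

    out = np.empty((len(images), input_size, input_size), dtype=np.float32)
    for i, img in enumerate(images):
        h, w = img.shape
        side = max(h, w)
        sq = np.zeros((side, side), dtype=float)
        r0 = (side - h) // 2
        c0 = (side - w) // 2
        sq[r0 : r0 + h, c0 : c0 + w] = img
        out[i] = resize(sq, (input_size, input_size), anti_aliasing=True, preserve_range=True)
    return out
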
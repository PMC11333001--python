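"""Convolutional triplet-embedding network, implemented directly on numpy.

The network maps a 150x170 log-power mel spectrogram to a d-dimensional
unit-norm embedding: a shared stack of strided convolution blocks
(convolution, batch normalisation, leaky ReLU) feeds two parallel pooling
branches — attention pooling (1x1-convolution logits, softmax over
time-frequency positions, attention-weighted channel sums) and global max
pooling — whose outputs are concatenated and projected by a dense layer,
then L2-normalised.  Forward and backward passes are written explicitly
(float64) and optimised with Adam; gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkConfig", "TripletNet"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the embedding network.

    ``blocks`` lists (channels, kernel, stride) per convolution block; the
    input shape is fixed at 1 x 150 x 170.
    """

    embedding_dim: int = 64
    blocks: tuple[tuple[int, int, int], ...] = (
        (16, 3, 2), (32, 3, 2), (64, 3, 2), (64, 3, 2),
    )
    leaky_slope: float = 0.01
    batch_norm: bool = True
    unit_normalise: bool = True
    input_shape: tuple[int, int] = (150, 170)
    input_pool: int = 1  # non-overlapping mean pooling applied to the input
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if not self.blocks:
            raise ValueError("need at least one conv block")
        if self.input_pool < 1:
            raise ValueError("input_pool must be >= 1")

    @classmethod
    def small(cls, embedding_dim: int = 16) -> "NetworkConfig":
        """Compact trunk used for CPU-scale synthetic experiments."""
        return cls(embedding_dim=embedding_dim, input_pool=2,
                   blocks=((8, 3, 4), (16, 3, 2), (16, 3, 2)),
                   dtype="float32")


# ---------------------------------------------------------------------------
# Layers.  Each stores params/grads in dicts and caches what backward needs.


class _Conv2d:
    def __init__(self, cin, cout, k, stride, rng):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.params = {
            "W": rng.normal(0.0, scale, size=(cout, cin * k * k)),
            "b": np.zeros(cout),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.pad = (k - 1) // 2

    def out_hw(self, h, w):
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def _im2col(self, x):
        n, c, h, w = x.shape
        ho, wo = self.out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        s = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, c, self.k, self.k, ho, wo),
            strides=(s[0], s[1], s[2], s[3], s[2] * self.stride, s[3] * self.stride),
            writeable=False,
        )
        return windows.reshape(n, c * self.k * self.k, ho * wo), (ho, wo)

    def forward(self, x, train):
        self._x_shape = x.shape
        cols, (ho, wo) = self._im2col(x)
        self._cols = cols
        out = np.einsum("ok,nkl->nol", self.params["W"], cols, optimize=True)
        out += self.params["b"][None, :, None]
        return out.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dout):
        n, _, ho, wo = dout.shape
        dflat = dout.reshape(n, self.cout, ho * wo)
        self.grads["W"][:] = np.einsum("nol,nkl->ok", dflat, self._cols, optimize=True)
        self.grads["b"][:] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("ok,nol->nkl", self.params["W"], dflat, optimize=True)
        # col2im
        _, c, h, w = self._x_shape
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dout.dtype)
        dcols = dcols.reshape(n, c, self.k, self.k, ho, wo)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + self.stride * ho : self.stride,
                    kj : kj + self.stride * wo : self.stride] += dcols[:, :, ki, kj]
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class _BatchNorm2d:
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        self._train = train
        return (self.params["gamma"][None, :, None, None] * self._xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dout):
        self.grads["gamma"][:] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][:] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not self._train:
            return dout * g * self._istd[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True))
        return term * self._istd[None, :, None, None]


class _LeakyReLU:
    def __init__(self, slope):
        self.slope = slope
        self.params = {}
        self.grads = {}

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class _AttentionPool:
    """1x1-conv attention logits, softmax over positions, weighted sum."""

    def __init__(self, c, rng):
        self.params = {"w": rng.normal(0.0, 1.0 / np.sqrt(c), size=c),
                       "b": np.zeros(1)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        n, c, h, w = x.shape
        xf = x.reshape(n, c, h * w)
        logits = np.einsum("ncl,c->nl", xf, self.params["w"]) + self.params["b"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        a = e / e.sum(axis=1, keepdims=True)
        self._xf, self._a, self._shape = xf, a, (n, c, h, w)
        return np.einsum("ncl,nl->nc", xf, a)

    def backward(self, dout):
        xf, a = self._xf, self._a
        n, c, h, w = self._shape
        dxf = a[:, None, :] * dout[:, :, None]
        da = np.einsum("ncl,nc->nl", xf, dout)
        dlogits = a * (da - (a * da).sum(axis=1, keepdims=True))
        self.grads["w"][:] = np.einsum("ncl,nl->c", xf, dlogits)
        self.grads["b"][:] = dlogits.sum()
        dxf += self.params["w"][None, :, None] * dlogits[:, None, :]
        return dxf.reshape(n, c, h, w)


class _GlobalMaxPool:
    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, train):
        n, c, h, w = x.shape
        xf = x.reshape(n, c, h * w)
        self._arg = xf.argmax(axis=2)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xf, self._arg[:, :, None], axis=2)[:, :, 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxf = np.zeros((n, c, h * w), dtype=dout.dtype)
        np.put_along_axis(dxf, self._arg[:, :, None], dout[:, :, None], axis=2)
        return dxf.reshape(n, c, h, w)


class _AvgPoolDown:
    """Non-overlapping p x p mean pooling (input down-sampling, no params)."""

    def __init__(self, p):
        self.p = p
        self.params = {}
        self.grads = {}

    def forward(self, x, train):
        p = self.p
        n, c, h, w = x.shape
        hp, wp = (h // p) * p, (w // p) * p
        self._in_shape = (n, c, h, w)
        x = x[:, :, :hp, :wp]
        return x.reshape(n, c, hp // p, p, wp // p, p).mean(axis=(3, 5))

    def backward(self, dout):
        p = self.p
        n, c, h, w = self._in_shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        up = np.repeat(np.repeat(dout, p, axis=2), p, axis=3) / (p * p)
        dx[:, :, : up.shape[2], : up.shape[3]] = up
        return dx


class _Dense:
    def __init__(self, cin, cout, rng):
        self.params = {"W": rng.normal(0.0, 1.0 / np.sqrt(cin), size=(cout, cin)),
                       "b": np.zeros(cout)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"][:] = dout.T @ self._x
        self.grads["b"][:] = dout.sum(axis=0)
        return dout @ self.params["W"]


# ---------------------------------------------------------------------------


@dataclass
class _AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0


class TripletNet:
    """The embedding network; see the module docstring for the topology."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self._dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        self.trunk = []
        cin = 1
        h, w = config.input_shape
        if config.input_pool > 1:
            self.trunk.append(_AvgPoolDown(config.input_pool))
            h, w = h // config.input_pool, w // config.input_pool
        for cout, k, stride in config.blocks:
            conv = _Conv2d(cin, cout, k, stride, rng)
            self.trunk.append(conv)
            if config.batch_norm:
                self.trunk.append(_BatchNorm2d(cout))
            self.trunk.append(_LeakyReLU(config.leaky_slope))
            h, w = conv.out_hw(h, w)
            cin = cout
        self.att = _AttentionPool(cin, rng)
        self.maxpool = _GlobalMaxPool()
        self.head = _Dense(2 * cin, config.embedding_dim, rng)
        self._adam = _AdamState()
        if self._dtype != np.float64:
            for layer in self._layers():
                for name in layer.params:
                    layer.params[name] = layer.params[name].astype(self._dtype)
                    layer.grads[name] = layer.grads[name].astype(self._dtype)
                if isinstance(layer, _BatchNorm2d):
                    layer.running_mean = layer.running_mean.astype(self._dtype)
                    layer.running_var = layer.running_var.astype(self._dtype)

    # -- forward / backward ------------------------------------------------

    def _layers(self):
        return [*self.trunk, self.att, self.maxpool, self.head]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Embed a batch: (N, 150, 170) or (N, 1, 150, 170) -> (N, d)."""
        x = np.asarray(x, dtype=self._dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2:] != self.config.input_shape:
            raise ValueError(
                f"input shape {x.shape[2:]} != expected {self.config.input_shape}"
            )
        for layer in self.trunk:
            x = layer.forward(x, train)
        a = self.att.forward(x, train)
        m = self.maxpool.forward(x, train)
        z = self.head.forward(np.concatenate([a, m], axis=1), train)
        if self.config.unit_normalise:
            self._norms = np.linalg.norm(z, axis=1, keepdims=True)
            self._norms = np.maximum(self._norms, 1e-12)
            self._z = z
            z = z / self._norms
            self._y = z
        return z

    def backward(self, dy: np.ndarray) -> None:
        dy = np.asarray(dy, dtype=self._dtype)
        if self.config.unit_normalise:
            y, nrm = self._y, self._norms
            dz = (dy - y * (y * dy).sum(axis=1, keepdims=True)) / nrm
        else:
            dz = dy
        dcat = self.head.backward(dz)
        c = dcat.shape[1] // 2
        dx = self.att.backward(dcat[:, :c]) + self.maxpool.backward(dcat[:, c:])
        for layer in reversed(self.trunk):
            dx = layer.backward(dx)

    def embed(self, mel) -> np.ndarray:
        """Embedding of a single 150x170 mel spectrogram (inference mode)."""
        values = getattr(mel, "values", mel)
        return self.forward(np.asarray(values)[None])[0]

    # -- optimisation ------------------------------------------------------

    def adam_step(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        st = self._adam
        st.t += 1
        for li, layer in enumerate(self._layers()):
            for name, p in layer.params.items():
                key = (li, name)
                g = layer.grads[name]
                if key not in st.m:
                    st.m[key] = np.zeros_like(p)
                    st.v[key] = np.zeros_like(p)
                st.m[key] = beta1 * st.m[key] + (1 - beta1) * g
                st.v[key] = beta2 * st.v[key] + (1 - beta2) * g * g
                mhat = st.m[key] / (1 - beta1 ** st.t)
                vhat = st.v[key] / (1 - beta2 ** st.t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- (de)serialisation -------------------------------------------------

    def state_dict(self) -> dict:
        out = {}
        for li, layer in enumerate(self._layers()):
            for name, p in layer.params.items():
                out[f"{li}.{name}"] = p.copy()
            if isinstance(layer, _BatchNorm2d):
                out[f"{li}.running_mean"] = layer.running_mean.copy()
                out[f"{li}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for li, layer in enumerate(self._layers()):
            for name in layer.params:
                layer.params[name][:] = state[f"{li}.{name}"]
            if isinstance(layer, _BatchNorm2d):
                layer.running_mean[:] = state[f"{li}.running_mean"]
                layer.running_var[:] = state[f"{li}.running_var"]

    def save(self, path) -> None:
        """Single-file checkpoint with the architecture embedded."""
        cfg = self.config
        np.savez(
            path,
            __embedding_dim=cfg.embedding_dim,
            __blocks=np.array(cfg.blocks),
            __leaky_slope=cfg.leaky_slope,
            __batch_norm=int(cfg.batch_norm),
            __unit_normalise=int(cfg.unit_normalise),
            __input_shape=np.array(cfg.input_shape),
            __input_pool=cfg.input_pool,
            __dtype=cfg.dtype,
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "TripletNet":
        with np.load(path) as data:
            cfg = NetworkConfig(
                embedding_dim=int(data["__embedding_dim"]),
                blocks=tuple(tuple(int(v) for v in row) for row in data["__blocks"]),
                leaky_slope=float(data["__leaky_slope"]),
                batch_norm=bool(data["__batch_norm"]),
                unit_normalise=bool(data["__unit_normalise"]),
                input_shape=tuple(int(v) for v in data["__input_shape"]),
                input_pool=int(data["__input_pool"]),
                dtype=str(data["__dtype"]),
            )
            model = cls(cfg)
            model.load_state_dict(
                {k: data[k] for k in data.files if not k.startswith("__")}
            )
        return model
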
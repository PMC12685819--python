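"""Layers with hand-derived backward passes.

Data layout is channels-last: convolutional/sequence tensors are
(batch, length, channels); dense tensors are (..., features).  Each layer
caches what its backward pass needs during forward; ``backward(dy)`` returns
the gradient with respect to the layer input and fills ``grads`` for its
parameters.  Composite layers (the transformer encoder block) namespace their
sub-parameters as ``sub/name``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "Conv1D", "BatchNorm1D", "MaxPool1D", "Dropout",
    "GlobalAvgPool1D", "Flatten", "LayerNorm", "MultiHeadSelfAttention",
    "TransformerEncoderLayer", "Sequential",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameters, gradients, optional non-trained buffers."""

    def __init__(self, name: str):
        self.name = name
        self.trainable = True
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # parameter traversal (flat, name-spaced) -------------------------------
    def param_items(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def grad_items(self) -> dict[str, np.ndarray]:
        return dict(self.grads)

    def state_items(self) -> dict[str, np.ndarray]:
        out = dict(self.params)
        out.update(self.buffers)
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            target = self.params if k in self.params else self.buffers
            if k not in target:
                raise KeyError(f"{self.name}: unknown state entry {k!r}")
            if target[k].shape != v.shape:
                raise ValueError(
                    f"{self.name}/{k}: shape {v.shape} != expected {target[k].shape}"
                )
            target[k] = v.astype(float).copy()

    def l2_loss(self) -> float:
        return 0.0

    def config(self) -> dict:
        return {}


class Dense(Layer):
    """Affine map on the last axis, optional ReLU, optional L2 penalty on W."""

    def __init__(self, n_in: int, n_out: int, *, activation: str | None = None,
                 l2: float = 0.0, name: str = "dense",
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.activation = activation
        self.l2 = l2
        self.params = {
            "W": _glorot(rng, (n_in, n_out), n_in, n_out),
            "b": np.zeros(n_out),
        }

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        x = self._x
        lead = x.reshape(-1, self.n_in)
        dyf = dy.reshape(-1, self.n_out)
        self.grads["W"] = lead.T @ dyf + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dyf.sum(axis=0)
        return dy @ self.params["W"].T

    def l2_loss(self) -> float:
        return float(self.l2 * np.sum(self.params["W"] ** 2))

    def config(self):
        return {"n_in": self.n_in, "n_out": self.n_out,
                "activation": self.activation, "l2": self.l2}


class Conv1D(Layer):
    """Same-padded 1-D convolution (stride 1, odd kernel), optional ReLU."""

    def __init__(self, c_in: int, filters: int, kernel: int = 3, *,
                 activation: str | None = "relu", l2: float = 0.0,
                 name: str = "conv", rng: np.random.Generator | None = None):
        super().__init__(name)
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.filters, self.kernel = c_in, filters, kernel
        self.activation = activation
        self.l2 = l2
        fan_in = kernel * c_in
        self.params = {
            "W": _glorot(rng, (kernel * c_in, filters), fan_in, filters),
            "b": np.zeros(filters),
        }

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, length, _ = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # win: (b, length, c_in, kernel) -> (b, length, kernel * c_in)
        return win.transpose(0, 1, 3, 2).reshape(b, length, self.kernel * self.c_in)

    def forward(self, x, training=False):
        self._shape = x.shape
        self._cols = self._im2col(x)
        y = self._cols @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        b, length, _ = self._shape
        cols = self._cols.reshape(-1, self.kernel * self.c_in)
        dyf = dy.reshape(-1, self.filters)
        self.grads["W"] = cols.T @ dyf + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dy @ self.params["W"].T).reshape(b, length, self.kernel, self.c_in)
        p = self.kernel // 2
        dxp = np.zeros((b, length + 2 * p, self.c_in))
        for k in range(self.kernel):
            dxp[:, k:k + length, :] += dcols[:, :, k, :]
        return dxp[:, p:p + length, :]

    def l2_loss(self) -> float:
        return float(self.l2 * np.sum(self.params["W"] ** 2))

    def config(self):
        return {"c_in": self.c_in, "filters": self.filters, "kernel": self.kernel,
                "activation": self.activation, "l2": self.l2}


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over batch (and time, if present)."""

    def __init__(self, channels: int, *, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        super().__init__(name)
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.buffers = {"running_mean": np.zeros(channels),
                        "running_var": np.ones(channels)}

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        self._training = training
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = m * self.buffers["running_mean"] + (1 - m) * mu
            self.buffers["running_var"] = m * self.buffers["running_var"] + (1 - m) * var
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xc = x - mu
        self._xhat = self._xc * self._ivar
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        if not self._training:  # eval: running stats are constants
            return dxhat * self._ivar
        n = self._n
        dvar = (dxhat * self._xc).sum(axis=axes) * (-0.5) * self._ivar ** 3
        dmu = -(dxhat.sum(axis=axes)) * self._ivar - 2.0 * dvar * self._xc.mean(axis=axes)
        return dxhat * self._ivar + (2.0 / n) * dvar * self._xc + dmu / n

    def config(self):
        return {"channels": self.channels, "momentum": self.momentum, "eps": self.eps}


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; an incomplete tail is dropped."""

    def __init__(self, pool: int = 2, name: str = "pool"):
        super().__init__(name)
        self.pool = pool

    def forward(self, x, training=False):
        b, length, c = x.shape
        n_out = length // self.pool
        if n_out < 1:
            raise ValueError(f"{self.name}: length {length} underflows pool {self.pool}")
        self._in_shape = x.shape
        xr = x[:, :n_out * self.pool, :].reshape(b, n_out, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        b, length, c = self._in_shape
        n_out = length // self.pool
        dxr = np.zeros((b, n_out, self.pool, c))
        bi, oi, ci = np.ogrid[:b, :n_out, :c]
        dxr[bi, oi, self._argmax, ci] = dy
        dx = np.zeros(self._in_shape)
        dx[:, :n_out * self.pool, :] = dxr.reshape(b, n_out * self.pool, c)
        return dx

    def config(self):
        return {"pool": self.pool}


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, name: str = "dropout"):
        super().__init__(name)
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def config(self):
        return {"p": self.p}


class GlobalAvgPool1D(Layer):
    """Mean over the time axis: (batch, length, channels) → (batch, channels)."""

    def __init__(self, name: str = "gap"):
        super().__init__(name)

    def forward(self, x, training=False):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._length, axis=1) / self._length


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__(name)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class LayerNorm(Layer):
    """Normalisation over the last axis with learned scale and shift."""

    def __init__(self, dim: int, *, eps: float = 1e-5, name: str = "ln"):
        super().__init__(name)
        self.dim, self.eps = dim, eps
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}

    def forward(self, x, training=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xc = x - mu
        self._xhat = self._xc * self._ivar
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        d = self.dim
        dxhat = dy * self.params["gamma"]
        # standard layer-norm backward over the last axis
        return (self._ivar / d) * (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=-1, keepdims=True)
        )

    def config(self):
        return {"dim": self.dim, "eps": self.eps}


def _softmax_last(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention; the last attention tensor
    (batch × heads × length × length) is kept on ``last_attention``."""

    def __init__(self, d_model: int, n_heads: int, *, name: str = "mha",
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        rng = rng or np.random.default_rng(0)
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.params = {}
        for w in ("Wq", "Wk", "Wv", "Wo"):
            self.params[w] = _glorot(rng, (d_model, d_model), d_model, d_model)
            self.params[w.replace("W", "b")] = np.zeros(d_model)
        self.last_attention: np.ndarray | None = None

    def _split(self, x):
        b, length, _ = x.shape
        return x.reshape(b, length, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x):
        b, h, length, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, length, h * dh)

    def forward(self, x, training=False):
        self._x = x
        p = self.params
        self._q = self._split(x @ p["Wq"] + p["bq"])
        self._k = self._split(x @ p["Wk"] + p["bk"])
        self._v = self._split(x @ p["Wv"] + p["bv"])
        scale = 1.0 / np.sqrt(self.d_head)
        scores = (self._q @ self._k.transpose(0, 1, 3, 2)) * scale
        self._attn = _softmax_last(scores)
        self.last_attention = self._attn
        self._ctx = self._merge(self._attn @ self._v)
        return self._ctx @ p["Wo"] + p["bo"]

    def backward(self, dy):
        p, g = self.params, self.grads
        b, length, d = dy.shape
        ctxf = self._ctx.reshape(-1, d)
        dyf = dy.reshape(-1, d)
        g["Wo"] = ctxf.T @ dyf
        g["bo"] = dyf.sum(axis=0)
        dctx = self._split(dy @ p["Wo"].T)

        dattn = dctx @ self._v.transpose(0, 1, 3, 2)
        dv = self._attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward per attention row
        dscores = self._attn * (dattn - (dattn * self._attn).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(self.d_head)
        dq = (dscores @ self._k) * scale
        dk = (dscores.transpose(0, 1, 3, 2) @ self._q) * scale

        xf = self._x.reshape(-1, d)
        dx = np.zeros_like(self._x)
        for W, bias, dproj in (("Wq", "bq", dq), ("Wk", "bk", dk), ("Wv", "bv", dv)):
            dflat = self._merge(dproj).reshape(-1, d)
            g[W] = xf.T @ dflat
            g[bias] = dflat.sum(axis=0)
            dx += (dflat @ p[W].T).reshape(self._x.shape)
        return dx

    def config(self):
        return {"d_model": self.d_model, "n_heads": self.n_heads}


class TransformerEncoderLayer(Layer):
    """Post-norm encoder block: x → LN(x + Drop(MHA(x))) → LN(h + Drop(FFN(h)))."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int, *,
                 dropout: float = 0.1, name: str = "enc",
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.d_model, self.n_heads, self.ffn_dim, self.dropout_p = (
            d_model, n_heads, ffn_dim, dropout)
        self.mha = MultiHeadSelfAttention(d_model, n_heads, name="mha", rng=rng)
        self.drop1 = Dropout(dropout, name="drop1")
        self.ln1 = LayerNorm(d_model, name="ln1")
        self.ffn1 = Dense(d_model, ffn_dim, activation="relu", name="ffn1", rng=rng)
        self.ffn2 = Dense(ffn_dim, d_model, name="ffn2", rng=rng)
        self.drop2 = Dropout(dropout, name="drop2")
        self.ln2 = LayerNorm(d_model, name="ln2")
        self._subs = [self.mha, self.drop1, self.ln1, self.ffn1, self.ffn2,
                      self.drop2, self.ln2]

    def set_rng(self, rng):
        for sub in self._subs:
            sub.set_rng(rng)

    def forward(self, x, training=False):
        a = self.drop1.forward(self.mha.forward(x, training), training)
        h = self.ln1.forward(x + a, training)
        f = self.drop2.forward(
            self.ffn2.forward(self.ffn1.forward(h, training), training), training)
        return self.ln2.forward(h + f, training)

    def backward(self, dy):
        dh_plus_f = self.ln2.backward(dy)
        df = self.drop2.backward(dh_plus_f)
        dh = dh_plus_f + self.ffn1.backward(self.ffn2.backward(df))
        dx_plus_a = self.ln1.backward(dh)
        da = self.drop1.backward(dx_plus_a)
        return dx_plus_a + self.mha.backward(da)

    def _ns(self, items_of) -> dict[str, np.ndarray]:
        out = {}
        for sub in self._subs:
            for k, v in items_of(sub).items():
                out[f"{sub.name}/{k}"] = v
        return out

    def param_items(self):
        return self._ns(lambda s: s.param_items())

    def grad_items(self):
        return self._ns(lambda s: s.grad_items())

    def state_items(self):
        return self._ns(lambda s: s.state_items())

    def load_state(self, state):
        by_sub: dict[str, dict[str, np.ndarray]] = {}
        for k, v in state.items():
            sub, _, rest = k.partition("/")
            by_sub.setdefault(sub, {})[rest] = v
        for sub in self._subs:
            if sub.name in by_sub:
                sub.load_state(by_sub[sub.name])

    def l2_loss(self):
        return sum(s.l2_loss() for s in self._subs)

    def config(self):
        return {"d_model": self.d_model, "n_heads": self.n_heads,
                "ffn_dim": self.ffn_dim, "dropout": self.dropout_p}


class Sequential:
    """An ordered stack of layers with uniquely named members.

    ``forward`` keeps every layer's output; ``backward`` can report the
    gradient arriving at each layer's output (used by the attribution
    methods) and the gradient with respect to the input.
    """

    def __init__(self, layers: list[Layer]):
        names = [lyr.name for lyr in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        self.layers = layers

    def __iter__(self):
        return iter(self.layers)

    def get(self, name: str) -> Layer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(f"no layer named {name!r}")

    def set_rng(self, rng: np.random.Generator) -> None:
        for lyr in self.layers:
            lyr.set_rng(rng)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self.outputs: dict[str, np.ndarray] = {}
        for lyr in self.layers:
            x = lyr.forward(x, training)
            self.outputs[lyr.name] = x
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate from the output; returns d(loss)/d(input) and stores
        d(loss)/d(layer output) per layer on ``boundary_grads``."""
        self.boundary_grads: dict[str, np.ndarray] = {}
        for lyr in reversed(self.layers):
            self.boundary_grads[lyr.name] = dy
            dy = lyr.backward(dy)
        return dy

    # flat, name-spaced traversal ------------------------------------------
    def _flat(self, items_of) -> dict[str, np.ndarray]:
        out = {}
        for lyr in self.layers:
            for k, v in items_of(lyr).items():
                out[f"{lyr.name}/{k}"] = v
        return out

    def param_items(self) -> dict[str, np.ndarray]:
        return self._flat(lambda l: l.param_items())

    def trainable_param_items(self) -> dict[str, np.ndarray]:
        out = {}
        for lyr in self.layers:
            if lyr.trainable:
                for k, v in lyr.param_items().items():
                    out[f"{lyr.name}/{k}"] = v
        return out

    def grad_items(self) -> dict[str, np.ndarray]:
        return self._flat(lambda l: l.grad_items())

    def state_items(self) -> dict[str, np.ndarray]:
        return self._flat(lambda l: l.state_items())

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        by_layer: dict[str, dict[str, np.ndarray]] = {}
        for k, v in state.items():
            lname, _, rest = k.partition("/")
            by_layer.setdefault(lname, {})[rest] = v
        for lyr in self.layers:
            if lyr.name in by_layer:
                lyr.load_state(by_layer[lyr.name])

    def l2_loss(self) -> float:
        return sum(lyr.l2_loss() for lyr in self.layers)

    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.param_items().values())
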
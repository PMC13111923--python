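"""Network layers with forward, backward and relevance-propagation hooks.

Tensor layout is ``[batch, maps, channels, time]`` throughout; the raw EEG
enters as ``[B, 1, C, T]``.  Every layer implements ``forward``/``backward``
for training.  Linear layers additionally expose the *structural* maps the
relevance rules need:

``lin(x, w)``
    the layer's linear action with an arbitrary weight array ``w`` (used
    with the positive/negative weight parts), bias excluded;
``lin_T(s, w)``
    the adjoint (transpose) of ``lin``.

Both preserve the dtype of their input, so relevance can run in float64
while training runs in float32.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as _k

__all__ = [
    "Layer", "TemporalConv", "DepthwiseSpatialConv", "DepthwiseTemporalConv",
    "PointwiseConv", "BatchNorm", "ELU", "ReLU", "AvgPool", "Dropout",
    "Flatten", "Dense", "CONV_KINDS", "LINEAR_KINDS",
]

CONV_KINDS = ("temporal_conv", "depthwise_spatial_conv",
              "separable_depthwise_conv", "pointwise_conv")
LINEAR_KINDS = CONV_KINDS + ("avg_pool", "dense")


class Layer:
    kind = "base"

    def __init__(self, name: str):
        self.name = name
        self._cache = None
        #: the trainer sets this False on the first layer (no input grad needed)
        self.requires_input_grad = True

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def forward_pure(self, x):
        """Eval-mode forward preserving dtype, no training caches touched."""
        return self.forward(x, training=False)

    def backward(self, g):
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def apply_constraints(self) -> None:
        pass

    def state(self) -> dict:
        return dict(self.params())

    def load_state(self, d: dict) -> None:
        for key, val in self.params().items():
            val[...] = d[key]

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params().values())


def _glorot(rng, shape, fan_in, fan_out, dtype=np.float32):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class TemporalConv(Layer):
    """Shared temporal kernels: [B,1,C,T] -> [B,F,C,T], 'same' padding."""

    kind = "temporal_conv"

    def __init__(self, f_out, kernel, rng, name="temporal_conv"):
        super().__init__(name)
        self.f_out = f_out
        self.kernel = kernel
        self.w = _glorot(rng, (f_out, kernel), kernel, kernel * f_out)
        self.b = None  # created by batch-norm folding
        self.gw = np.zeros_like(self.w)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def _pad(self, x3):
        return np.pad(x3, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))

    def forward(self, x, training=False, rng=None):
        B, one, C, T = x.shape
        xpad = self._pad(x[:, 0])
        y = _k.tconv_fwd(xpad, self.w.astype(x.dtype, copy=False), T)
        if training:
            self._cache = (xpad, T)
        if self.b is not None:
            y = y + self.b.astype(x.dtype)[None, :, None, None]
        return y

    def backward(self, g):
        xpad, T = self._cache
        self.gw = _k.tconv_gradw(xpad, g)
        if self.b is not None:
            raise RuntimeError("folded (biased) models are not trainable")
        if not self.requires_input_grad:
            self._cache = None
            return None
        gx = _k.tconv_gradx(self.w, g, xpad.shape[-1])
        gx = gx[..., self.pad_left: self.pad_left + T]
        self._cache = None
        return gx[:, None]

    def lin(self, x, w):
        xpad = self._pad(np.ascontiguousarray(x[:, 0]))
        return _k.tconv_fwd(xpad, np.ascontiguousarray(w.astype(x.dtype, copy=False)),
                            x.shape[-1])

    def lin_T(self, s, w):
        s = np.ascontiguousarray(s)
        L = s.shape[-1] + self.kernel - 1
        gx = _k.tconv_gradx(np.ascontiguousarray(w.astype(s.dtype, copy=False)), s, L)
        return gx[..., self.pad_left: self.pad_left + s.shape[-1]][:, None]

    def params(self):
        return {"w": self.w}

    def grads(self):
        return {"w": self.gw}

    def state(self):
        d = {"w": self.w}
        if self.b is not None:
            d["b"] = self.b
        return d

    def load_state(self, d):
        self.w[...] = d["w"]
        self.b = np.asarray(d["b"]) if "b" in d else None


class DepthwiseSpatialConv(Layer):
    """Per-temporal-filter spatial kernels: [B,F1,C,T] -> [B,F1*D,1,T]."""

    kind = "depthwise_spatial_conv"

    def __init__(self, f_in, depth, n_channels, rng, max_norm=1.0,
                 name="spatial_conv"):
        super().__init__(name)
        self.f_in, self.depth, self.n_channels = f_in, depth, n_channels
        self.w = _glorot(rng, (f_in, depth, n_channels),
                         n_channels, n_channels * depth)
        self.b = None
        self.gw = np.zeros_like(self.w)
        self.max_norm = max_norm

    def forward(self, x, training=False, rng=None):
        if training:
            self._cache = x
        y = self.lin(x, self.w)
        if self.b is not None:
            y = y + self.b.astype(x.dtype)[None, :, None, None]
        return y

    def backward(self, g):
        x = self._cache
        B = g.shape[0]
        T = g.shape[-1]
        g4 = np.ascontiguousarray(g.reshape(B, self.f_in, self.depth, T))
        self.gw = _k.spatial_bwd_gw(x, g4)
        self._cache = None
        if not self.requires_input_grad:
            return None
        return _k.spatial_bwd_gx(self.w.astype(g.dtype, copy=False), g4)

    def lin(self, x, w):
        y = _k.spatial_fwd(np.ascontiguousarray(x),
                           np.ascontiguousarray(w.astype(x.dtype, copy=False)))
        B = y.shape[0]
        return y.reshape(B, -1, 1, y.shape[-1])

    def lin_T(self, s, w):
        B = s.shape[0]
        T = s.shape[-1]
        s4 = np.ascontiguousarray(s.reshape(B, self.f_in, self.depth, T))
        return _k.spatial_bwd_gx(
            np.ascontiguousarray(w.astype(s.dtype, copy=False)), s4)

    def apply_constraints(self):
        if self.max_norm is None:
            return
        norms = np.sqrt((self.w ** 2).sum(axis=2, keepdims=True))
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.w *= factor.astype(self.w.dtype)

    def params(self):
        return {"w": self.w}

    def grads(self):
        return {"w": self.gw}

    def state(self):
        d = {"w": self.w}
        if self.b is not None:
            d["b"] = self.b
        return d

    def load_state(self, d):
        self.w[...] = d["w"]
        self.b = np.asarray(d["b"]) if "b" in d else None


class DepthwiseTemporalConv(Layer):
    """Per-map temporal kernels (separable block): [B,F,1,T] -> [B,F,1,T]."""

    kind = "separable_depthwise_conv"

    def __init__(self, f_maps, kernel, rng, name="sep_depthwise"):
        super().__init__(name)
        self.f_maps, self.kernel = f_maps, kernel
        self.w = _glorot(rng, (f_maps, kernel), kernel, kernel)
        self.b = None
        self.gw = np.zeros_like(self.w)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def _corr(self, x, w):
        # x [B,F,1,T]; per-map cross-correlation via K shifted adds
        T = x.shape[-1]
        xpad = np.pad(x[:, :, 0], ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        y = np.zeros_like(x[:, :, 0])
        for k in range(self.kernel):
            y += w[None, :, k] [..., None] * xpad[..., k: k + T]
        return y[:, :, None]

    def _corr_T(self, s, w):
        T = s.shape[-1]
        gx = np.zeros((s.shape[0], s.shape[1], T + self.kernel - 1), dtype=s.dtype)
        for k in range(self.kernel):
            gx[..., k: k + T] += w[None, :, k][..., None] * s[:, :, 0]
        return gx[..., self.pad_left: self.pad_left + T][:, :, None]

    def forward(self, x, training=False, rng=None):
        if training:
            self._cache = x
        y = self._corr(x, self.w.astype(x.dtype, copy=False))
        if self.b is not None:
            y = y + self.b.astype(x.dtype)[None, :, None, None]
        return y

    def backward(self, g):
        x = self._cache
        T = x.shape[-1]
        xpad = np.pad(x[:, :, 0], ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        gw = np.empty_like(self.w)
        for k in range(self.kernel):
            gw[:, k] = (g[:, :, 0] * xpad[..., k: k + T]).sum(axis=(0, 2))
        self.gw = gw
        self._cache = None
        if not self.requires_input_grad:
            return None
        return self._corr_T(g, self.w.astype(g.dtype, copy=False))

    def lin(self, x, w):
        return self._corr(x, w.astype(x.dtype, copy=False))

    def lin_T(self, s, w):
        return self._corr_T(s, w.astype(s.dtype, copy=False))

    def params(self):
        return {"w": self.w}

    def grads(self):
        return {"w": self.gw}

    def state(self):
        d = {"w": self.w}
        if self.b is not None:
            d["b"] = self.b
        return d

    def load_state(self, d):
        self.w[...] = d["w"]
        self.b = np.asarray(d["b"]) if "b" in d else None


class PointwiseConv(Layer):
    """1x1 map-mixing convolution: [B,Fin,1,T] -> [B,Fout,1,T]."""

    kind = "pointwise_conv"

    def __init__(self, f_in, f_out, rng, name="pointwise_conv"):
        super().__init__(name)
        self.f_in, self.f_out = f_in, f_out
        self.w = _glorot(rng, (f_out, f_in), f_in, f_out)
        self.b = None
        self.gw = np.zeros_like(self.w)

    def forward(self, x, training=False, rng=None):
        if training:
            self._cache = x
        y = np.einsum("oi,bict->boct", self.w.astype(x.dtype, copy=False), x)
        if self.b is not None:
            y = y + self.b.astype(x.dtype)[None, :, None, None]
        return y

    def backward(self, g):
        x = self._cache
        self.gw = np.einsum("boct,bict->oi", g, x)
        self._cache = None
        if not self.requires_input_grad:
            return None
        return np.einsum("oi,boct->bict", self.w.astype(g.dtype, copy=False), g)

    def lin(self, x, w):
        return np.einsum("oi,bict->boct", w.astype(x.dtype, copy=False), x)

    def lin_T(self, s, w):
        return np.einsum("oi,boct->bict", w.astype(s.dtype, copy=False), s)

    def params(self):
        return {"w": self.w}

    def grads(self):
        return {"w": self.gw}

    def state(self):
        d = {"w": self.w}
        if self.b is not None:
            d["b"] = self.b
        return d

    def load_state(self, d):
        self.w[...] = d["w"]
        self.b = np.asarray(d["b"]) if "b" in d else None


class BatchNorm(Layer):
    """Per-map batch normalization over (batch, channels, time)."""

    kind = "batchnorm"

    def __init__(self, n_maps, momentum=0.99, eps=1e-3, name="bn"):
        super().__init__(name)
        self.n_maps = n_maps
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(n_maps, np.float32)
        self.beta = np.zeros(n_maps, np.float32)
        self.running_mean = np.zeros(n_maps, np.float64)
        self.running_var = np.ones(n_maps, np.float64)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def forward(self, x, training=False, rng=None):
        B, F, C, T = x.shape
        x3 = np.ascontiguousarray(x.reshape(B, F, C * T))
        if training:
            s1, s2 = _k.bn_stats(x3)
            n = B * C * T
            mu = s1 / n
            var = np.maximum(s2 / n - mu ** 2, 0.0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
            self._cache = (x3, mu, 1.0 / np.sqrt(var + self.eps), (B, F, C, T))
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        scale = (self.gamma * inv_sd).astype(x.dtype)
        shift = (self.beta - self.gamma * mu * inv_sd).astype(x.dtype)
        y = _k.bn_apply(x3, scale, shift)
        return y.reshape(B, F, C, T)

    def backward(self, g):
        x3, mu, inv_sd, shape = self._cache
        B, F, C, T = shape
        g3 = np.ascontiguousarray(g.reshape(B, F, C * T))
        n = B * C * T
        sg, sgx = _k.bn_bwd_sums(g3, x3, mu, inv_sd)
        self.gbeta = sg.astype(np.float32)
        self.ggamma = sgx.astype(np.float32)
        dx = _k.bn_bwd_dx(g3, x3, mu, inv_sd,
                          self.gamma.astype(np.float64), sg / n, sgx / n)
        self._cache = None
        return dx.reshape(B, F, C, T)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}

    def state(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean,
                "running_var": self.running_var}

    def load_state(self, d):
        self.gamma[...] = d["gamma"]
        self.beta[...] = d["beta"]
        self.running_mean[...] = d["running_mean"]
        self.running_var[...] = d["running_var"]


class ELU(Layer):
    kind = "elu"

    def __init__(self, alpha=1.0, name="elu"):
        super().__init__(name)
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        if training:
            self._cache = (x, y)
        return y

    def backward(self, g):
        x, y = self._cache
        self._cache = None
        return g * np.where(x > 0, 1.0, y + self.alpha).astype(g.dtype)


class ReLU(Layer):
    kind = "relu"

    def __init__(self, name="relu"):
        super().__init__(name)

    def forward(self, x, training=False, rng=None):
        if training:
            self._cache = x
        return np.maximum(x, 0)

    def backward(self, g):
        x = self._cache
        self._cache = None
        return g * (x > 0)


class AvgPool(Layer):
    """Non-overlapping average pooling over the time axis."""

    kind = "avg_pool"

    def __init__(self, pool, name="pool"):
        super().__init__(name)
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        B, F, C, T = x.shape
        if T % self.pool:
            raise ValueError(f"time axis {T} not divisible by pool {self.pool}")
        return x.reshape(B, F, C, T // self.pool, self.pool).mean(axis=-1)

    def backward(self, g):
        return np.repeat(g, self.pool, axis=-1) / self.pool

    def lin(self, x, w=None):
        return self.forward(x)

    def lin_T(self, s, w=None):
        return np.repeat(s, self.pool, axis=-1) / self.pool


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, rate, name="dropout"):
        super().__init__(name)
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = (rng.random(x.shape) >= self.rate).astype(x.dtype)
        self._cache = mask
        return x * mask / (1.0 - self.rate)

    def backward(self, g):
        mask = self._cache
        self._cache = None
        return g * mask / (1.0 - self.rate)


class Flatten(Layer):
    kind = "flatten"

    def __init__(self, name="flatten"):
        super().__init__(name)

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    kind = "dense"

    def __init__(self, n_in, n_out, rng, bias=True, max_norm=0.25, name="dense"):
        super().__init__(name)
        self.w = _glorot(rng, (n_out, n_in), n_in, n_out)
        self.b = np.zeros(n_out, np.float32) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros(n_out, np.float32) if bias else None
        self.max_norm = max_norm

    def forward(self, x, training=False, rng=None):
        if training:
            self._cache = x
        y = x @ self.w.astype(x.dtype, copy=False).T
        if self.b is not None:
            y = y + self.b.astype(x.dtype)
        return y

    def backward(self, g):
        x = self._cache
        self.gw = g.T @ x
        if self.b is not None:
            self.gb = g.sum(axis=0).astype(np.float32)
        self._cache = None
        return g @ self.w.astype(g.dtype, copy=False)

    def lin(self, x, w):
        return x @ w.astype(x.dtype, copy=False).T

    def lin_T(self, s, w):
        return s @ w.astype(s.dtype, copy=False)

    def apply_constraints(self):
        if self.max_norm is None:
            return
        norms = np.sqrt((self.w ** 2).sum(axis=1, keepdims=True))
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.w *= factor.astype(self.w.dtype)

    def params(self):
        p = {"w": self.w}
        if self.b is not None:
            p["b"] = self.b
        return p

    def grads(self):
        g = {"w": self.gw}
        if self.b is not None:
            g["b"] = self.gb
        return g
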
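"""EEGNet-style model container.

The architecture is the compact depthwise-separable CNN of Lawhern et al.'s
EEGNet with its default hyperparameters: F1=8 temporal filters (64-sample
kernels at 128 Hz), D=2 spatial filters per temporal filter, a separable
block with 16-sample depthwise kernels and F2=16 pointwise filters, ELU
activations, average pooling by 4 then 8, dropout 0.25, and a 2-class dense
head.  The pointwise convolution is the network's last convolutional layer
and the unit of concept analysis (16 filters).
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool, BatchNorm, Dense, DepthwiseSpatialConv,
                     DepthwiseTemporalConv, Dropout, ELU, Flatten, Layer,
                     PointwiseConv, TemporalConv, CONV_KINDS)

__all__ = ["LayerGraph", "build_eegnet", "forward_activations",
           "LAST_CONV_LAYER"]

#: name of the last convolutional layer (the 16-filter pointwise conv)
LAST_CONV_LAYER = "pointwise_conv"


class LayerGraph:
    """An ordered stack of layers with a [B, C, T] -> logits forward pass."""

    def __init__(self, layers: list[Layer], n_channels: int, n_times: int,
                 hyper: dict | None = None):
        self.layers = layers
        self.n_channels = n_channels
        self.n_times = n_times
        self.hyper = hyper or {}
        if layers:
            layers[0].requires_input_grad = False

    def __getitem__(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def layer_index(self, name: str) -> int:
        for i, layer in enumerate(self.layers):
            if layer.name == name:
                return i
        raise KeyError(name)

    def _to_input(self, x, dtype=np.float32):
        x = np.asarray(x)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.n_channels, self.n_times):
            raise ValueError(
                f"expected input [n, {self.n_channels}, {self.n_times}], "
                f"got {x.shape}")
        return np.ascontiguousarray(x[:, None], dtype=dtype)

    def forward(self, x, training=False, rng=None):
        """Logits [B, n_classes] for epochs x [B, C, T]."""
        h = self._to_input(x)
        for layer in self.layers:
            h = layer.forward(h, training=training, rng=rng)
        return h

    def forward_trace(self, x, dtype=np.float64):
        """Eval-mode forward returning each layer's input (for relevance)."""
        h = self._to_input(x, dtype=dtype)
        inputs = []
        for layer in self.layers:
            inputs.append(h)
            h = layer.forward_pure(h)
        return inputs, h

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, x):
        logits = self.forward(x)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x):
        return self.forward(x).argmax(axis=1)

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def trainable_layers(self):
        return [layer for layer in self.layers if layer.params()]


def build_eegnet(n_channels: int, n_times: int, *, f1: int = 8, d: int = 2,
                 f2: int = 16, kt: int = 64, ks: int = 16, pool1: int = 4,
                 pool2: int = 8, dropout: float = 0.25, n_classes: int = 2,
                 dense_bias: bool = True, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> LayerGraph:
    """Build an EEGNet with freshly initialized weights.

    Two builds with the same ``seed`` produce identical weights.  With
    ``dense_bias=False`` the whole network is bias-free after batch-norm
    folding of an untrained model, which the relevance conservation checks
    rely on.
    """
    if n_times < kt:
        raise ValueError("n_times must be at least the temporal kernel length")
    if n_times % (pool1 * pool2):
        raise ValueError("n_times must be divisible by pool1*pool2")
    if rng is None:
        rng = np.random.default_rng(seed)
    map_len = n_times // (pool1 * pool2)
    layers = [
        TemporalConv(f1, kt, rng, name="temporal_conv"),
        BatchNorm(f1, name="bn1"),
        DepthwiseSpatialConv(f1, d, n_channels, rng, name="spatial_conv"),
        BatchNorm(f1 * d, name="bn2"),
        ELU(name="elu1"),
        AvgPool(pool1, name="pool1"),
        Dropout(dropout, name="drop1"),
        DepthwiseTemporalConv(f1 * d, ks, rng, name="sep_depthwise"),
        PointwiseConv(f1 * d, f2, rng, name="pointwise_conv"),
        BatchNorm(f2, name="bn3"),
        ELU(name="elu2"),
        AvgPool(pool2, name="pool2"),
        Dropout(dropout, name="drop2"),
        Flatten(name="flatten"),
        Dense(f2 * map_len, n_classes, rng, bias=dense_bias, name="dense"),
    ]
    hyper = dict(f1=f1, d=d, f2=f2, kt=kt, ks=ks, pool1=pool1, pool2=pool2,
                 dropout=dropout, n_classes=n_classes, map_len=map_len)
    return LayerGraph(layers, n_channels, n_times, hyper)


def forward_activations(model: LayerGraph, x, layer_id: str) -> np.ndarray:
    """Activation maps [n, n_filters, map_len] at a convolutional layer.

    Runs the forward pass truncated just after ``layer_id`` (inclusive).
    """
    idx = model.layer_index(layer_id)
    layer = model.layers[idx]
    if layer.kind not in CONV_KINDS:
        raise ValueError(f"layer {layer_id!r} is not convolutional "
                         f"(kind={layer.kind!r})")
    h = model._to_input(x)
    for lay in model.layers[: idx + 1]:
        h = lay.forward(h, training=False)
    n, f = h.shape[0], h.shape[1]
    return h.reshape(n, f, -1)
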
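"""Layer-wise and concept-conditioned relevance propagation (LRP / CRP).

LRP redistributes a model's class score backwards through the network under
a local conservation principle: the relevance :math:`R_k` of an output
neuron is split over its inputs proportionally to their contributions
:math:`z_{jk} = a_j w_{jk}`.  The engine implements the three classic rules

* LRP-0: share proportional to :math:`z_{jk}`,
* LRP-ε: a stabilizing ε in the denominator,
* LRP-αβ: positive and negative contributions weighted separately with
  :math:`\\alpha - \\beta = 1`,

and applies them per layer kind through a :class:`Composite` (default:
α2β1 on all convolutions, ε on dense and pooling layers, the ε-α2-β1
composite that emphasizes positive evidence).

CRP extends LRP with a conditioning set θ: at a chosen layer, relevance
flowing through filters outside θ is zeroed, isolating the concept encoded
by the selected filters.  Because every propagation rule is linear in the
incoming relevance (the forward activations are fixed), CRP heatmaps over
disjoint filter sets add up exactly to the unconditioned LRP heatmap.

Propagation requires a *canonical* model: batch normalization folded into
the adjacent convolution so each layer is purely linear (+bias) or an
elementwise nonlinearity.  ELU and dropout are relevance-transparent.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn.layers import (BatchNorm, DepthwiseSpatialConv, DepthwiseTemporalConv,
                        PointwiseConv, TemporalConv, CONV_KINDS)
from .nn.model import LayerGraph, LAST_CONV_LAYER

__all__ = ["Condition", "RelevanceTensor", "Composite", "canonicalize",
           "propagate_layer", "lrp", "crp"]


@dataclass(frozen=True)
class Condition:
    """CRP conditioning set: (layer, filter subset θ, output class)."""

    layer_id: str = LAST_CONV_LAYER
    filters: tuple[int, ...] = ()
    class_y: int = 0

    def validate(self, model: LayerGraph) -> None:
        layer = model[self.layer_id]
        if layer.kind not in CONV_KINDS:
            raise ValueError(f"condition layer {self.layer_id!r} is not "
                             "convolutional")
        if len(self.filters) == 0:
            raise ValueError("condition filter set θ must be non-empty")
        n_f = layer.w.shape[0] if layer.kind != "depthwise_spatial_conv" \
            else layer.f_in * layer.depth
        for f in self.filters:
            if not 0 <= f < n_f:
                raise ValueError(f"filter index {f} out of range [0, {n_f})")


@dataclass
class RelevanceTensor:
    """Relevance values co-shaped with a representation, with a domain tag."""

    values: np.ndarray
    domain: str  # 'time' | 'frequency'

    def __post_init__(self):
        if self.domain not in ("time", "frequency"):
            raise ValueError("domain must be 'time' or 'frequency'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("relevance contains non-finite values")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def per_sample_total(self) -> np.ndarray:
        return self.values.reshape(self.values.shape[0], -1).sum(axis=1)


@dataclass(frozen=True)
class Composite:
    """Layer-kind -> rule map.  Rules: ('lrp0',), ('epsilon', eps),
    ('alphabeta', alpha, beta) with alpha - beta = 1."""

    rules: dict = field(default_factory=lambda: {
        "temporal_conv": ("alphabeta", 2.0, 1.0),
        "depthwise_spatial_conv": ("alphabeta", 2.0, 1.0),
        "separable_depthwise_conv": ("alphabeta", 2.0, 1.0),
        "pointwise_conv": ("alphabeta", 2.0, 1.0),
        "avg_pool": ("epsilon", 1e-6),
        "dense": ("epsilon", 1e-6),
    })

    def __post_init__(self):
        for kind, rule in self.rules.items():
            if rule[0] == "alphabeta":
                _, a, b = rule
                if abs(a - b - 1.0) > 1e-12:
                    raise ValueError("alphabeta rule requires alpha - beta = 1")
            elif rule[0] == "epsilon":
                if rule[1] <= 0:
                    raise ValueError("epsilon must be > 0")
            elif rule[0] != "lrp0":
                raise ValueError(f"unknown rule {rule[0]!r}")

    def rule_for(self, kind: str):
        return self.rules[kind]

    @staticmethod
    def all_lrp0() -> "Composite":
        return Composite({kind: ("lrp0",) for kind in
                          ("temporal_conv", "depthwise_spatial_conv",
                           "separable_depthwise_conv", "pointwise_conv",
                           "avg_pool", "dense")})


def canonicalize(model: LayerGraph) -> LayerGraph:
    """Fold batch-norm layers into the preceding convolution.

    Uses the running statistics (inference mode).  The returned model has no
    batch-norm layers; forward outputs agree with the original inference
    pass to numerical precision.  Idempotent.
    """
    new_layers = []
    for layer in model.layers:
        if isinstance(layer, BatchNorm):
            if not new_layers or new_layers[-1].kind not in CONV_KINDS:
                raise ValueError("batch-norm not preceded by a foldable "
                                 "convolution")
            conv = new_layers[-1]
            inv_sd = 1.0 / np.sqrt(layer.running_var + layer.eps)
            scale = (layer.gamma * inv_sd).astype(np.float64)
            shift = (layer.beta - layer.gamma * layer.running_mean * inv_sd
                     ).astype(np.float64)
            if isinstance(conv, DepthwiseSpatialConv):
                sc = scale.reshape(conv.f_in, conv.depth)
                conv.w = (conv.w.astype(np.float64)
                          * sc[:, :, None]).astype(np.float32)
            elif isinstance(conv, (TemporalConv, DepthwiseTemporalConv,
                                   PointwiseConv)):
                conv.w = (conv.w.astype(np.float64)
                          * scale[:, None]).astype(np.float32)
            else:  # pragma: no cover - guarded above
                raise ValueError(f"cannot fold into {conv.kind}")
            old_b = conv.b if conv.b is not None else 0.0
            b = np.asarray(old_b, dtype=np.float64) * scale + shift
            conv.b = None if np.allclose(b, 0.0, atol=0.0) else b
        else:
            new_layers.append(copy.deepcopy(layer))
    return LayerGraph(new_layers, model.n_channels, model.n_times,
                      dict(model.hyper))


def _per_sample_scale(z: np.ndarray) -> np.ndarray:
    axes = tuple(range(1, z.ndim))
    scale = np.abs(z).mean(axis=axes, keepdims=True)
    return np.maximum(scale, 1e-30)


def _bias(layer, like):
    if getattr(layer, "b", None) is None:
        return None
    b = np.asarray(layer.b, dtype=like.dtype)
    if like.ndim == 4:
        return b[None, :, None, None]
    return b[None, :]


def propagate_layer(rule, layer, a: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Redistribute upper-layer relevance R through one linear layer.

    ``a`` is the layer's input activation; the layer's own weights (and
    absorbed bias, if any) define the contributions.  For the αβ rule with
    bias-free layers the redistribution conserves the total exactly.
    """
    name = rule[0]
    w = getattr(layer, "w", None)
    if name in ("epsilon", "lrp0"):
        z = layer.lin(a, w)
        b = _bias(layer, z)
        if b is not None:
            z = z + b
        eps = rule[1] if name == "epsilon" else 1e-12
        stab = eps * _per_sample_scale(z)
        s = R / (z + np.where(z >= 0, 1.0, -1.0) * stab)
        return a * layer.lin_T(s, w)
    if name == "alphabeta":
        _, alpha, beta = rule
        ap = np.maximum(a, 0.0)
        an = a - ap
        wp = np.maximum(w, 0.0)
        wn = w - wp
        zp = layer.lin(ap, wp) + layer.lin(an, wn)
        zn = layer.lin(ap, wn) + layer.lin(an, wp)
        b = _bias(layer, zp)
        if b is not None:
            zp = zp + np.maximum(b, 0.0)
            zn = zn + np.minimum(b, 0.0)
        # Outputs where one sign part is absent route their whole relevance
        # through the other part with net weight alpha - beta = 1, keeping
        # the redistribution exactly conserving for bias-free layers.
        tol = 1e-12 * _per_sample_scale(zp - zn)
        pos_only = zn >= -tol
        neg_only = zp <= tol
        alpha_eff = np.where(pos_only, alpha - beta, alpha)
        beta_eff = np.where(pos_only, 0.0, beta)
        alpha_eff = np.where(neg_only, 0.0, alpha_eff)
        beta_eff = np.where(neg_only, beta - alpha, beta_eff)
        stab = 1e-12 * _per_sample_scale(zp)
        sp = alpha_eff * R / (zp + stab)
        sn = beta_eff * R / (zn - stab)
        r_pos = ap * layer.lin_T(sp, wp) + an * layer.lin_T(sp, wn)
        r_neg = ap * layer.lin_T(sn, wn) + an * layer.lin_T(sn, wp)
        return r_pos - r_neg
    raise ValueError(f"unknown rule {name!r}")


def _relevance_backward(model: LayerGraph, inputs: list, R: np.ndarray,
                        composite: Composite,
                        mask_after: int | None = None,
                        filters: tuple[int, ...] = ()) -> np.ndarray:
    for i in reversed(range(len(model.layers))):
        layer = model.layers[i]
        if mask_after is not None and i == mask_after:
            mask = np.zeros(R.shape[1], dtype=R.dtype)
            mask[list(filters)] = 1.0
            R = R * mask[None, :, None, None]
        a = inputs[i]
        kind = layer.kind
        if kind == "batchnorm":
            raise ValueError("canonicalize the model before propagation")
        if kind in ("elu", "relu", "dropout"):
            pass  # relevance-transparent
        elif kind == "flatten":
            R = R.reshape(a.shape)
        elif kind in composite.rules:
            R = propagate_layer(composite.rule_for(kind), layer, a, R)
        else:  # pragma: no cover
            raise ValueError(f"no rule for layer kind {kind!r}")
    return R


def _init_relevance(logits: np.ndarray, class_y: int,
                    init: str = "logit") -> np.ndarray:
    """Output-layer seed: the class logit, or its margin over the others.

    ``init='logit'`` seeds with the raw logit of ``class_y``.
    ``init='margin'`` seeds with the logit minus the mean of the other
    classes' logits: the softmax is invariant to common shifts of the
    logits, so the margin is the part of the output the classifier's
    decision actually depends on.
    """
    R = np.zeros_like(logits)
    if init == "logit":
        R[:, class_y] = logits[:, class_y]
    elif init == "margin":
        # explain f_y - mean(f_others): both output neurons are seeded, so
        # relevance flows through the competing class's weights with
        # opposite sign and the common mode of the logits cancels
        n_other = logits.shape[1] - 1
        R[:] = -logits / n_other
        R[:, class_y] = logits[:, class_y]
    else:
        raise ValueError("init must be 'logit' or 'margin'")
    return R


def lrp(model: LayerGraph, x, class_y: int,
        composite: Composite | None = None,
        init: str = "logit") -> RelevanceTensor:
    """Input-space relevance heatmap for the class score of ``class_y``.

    ``x`` is one epoch [C, T] or a batch [n, C, T]; the heatmap is co-shaped
    with the batch form [n, C, T].  ``init`` chooses the output seed (raw
    logit, or the decision margin for discriminative explanations).
    """
    composite = composite or Composite()
    inputs, logits = model.forward_trace(x)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite activations in forward pass")
    R = _relevance_backward(model, inputs,
                            _init_relevance(logits, class_y, init),
                            composite)
    return RelevanceTensor(values=R[:, 0], domain="time")


def crp(model: LayerGraph, x, condition: Condition,
        composite: Composite | None = None,
        init: str = "logit") -> RelevanceTensor:
    """Concept-conditioned relevance: LRP with relevance restricted to the
    filters θ of the condition layer."""
    composite = composite or Composite()
    condition.validate(model)
    idx = model.layer_index(condition.layer_id)
    inputs, logits = model.forward_trace(x)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite activations in forward pass")
    R = _relevance_backward(model, inputs,
                            _init_relevance(logits, condition.class_y, init),
                            composite, mask_after=idx,
                            filters=condition.filters)
    return RelevanceTensor(values=R[:, 0], domain="time")
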
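"""Relevance maximization: concept-representative samples per filter.

For a condition (filter, class), every held-out test sample of that class
is scored by the signed sum of its CRP heatmap.  The concept's
representatives are the top-scoring samples whose cumulative relevance mass
reaches a fraction (default 20%) of the total positive mass, capped at 10
samples — mirroring the observation that per-unit relevance is concentrated
on few samples.  The concept itself is represented by the mean activation
map of the conditioned filter over the selected samples, plus the mean
frequency-domain relevance for the spectral views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .crp import Composite, Condition, crp
from .nn.model import LayerGraph, forward_activations, LAST_CONV_LAYER
from .synthetic import EpochSet
from .vil import FreqRelevance, VILModel, project_time_relevance

__all__ = ["Concept", "score_samples", "select_top_k", "build_concept",
           "concepts_for_model"]

logger = logging.getLogger(__name__)


@dataclass
class Concept:
    """One (model, filter, class) unit with its representative samples."""

    model_id: str
    layer_id: str
    filter_id: int
    class_y: int
    sample_ids: np.ndarray  # epoch indices into the scored EpochSet
    sample_relevance: np.ndarray  # signed relevance sums of the selected
    mean_activation_map: np.ndarray  # [map_len]
    mean_freq_relevance: FreqRelevance | None = None
    extras: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.sample_ids)

    @property
    def empty(self) -> bool:
        return self.k == 0


def score_samples(model: LayerGraph, epochs: EpochSet, condition: Condition,
                  composite: Composite | None = None, *,
                  return_heatmaps: bool = False):
    """Signed per-sample relevance sums for samples of the condition class.

    Returns ``(sample_ids, scores)`` where sample_ids index into ``epochs``.
    Only samples whose label equals the condition class are scored.  With
    ``return_heatmaps`` the CRP heatmaps themselves are returned as well, so
    callers that need them (e.g. for frequency projection of the selected
    samples) avoid a second backward pass.
    """
    ids = np.flatnonzero(epochs.labels == condition.class_y)
    if len(ids) == 0:
        raise ValueError(f"no samples of class {condition.class_y}")
    rt = crp(model, epochs.data[ids], condition, composite)
    scores = rt.per_sample_total()
    if return_heatmaps:
        return ids, scores, rt
    return ids, scores


def select_top_k(scores: np.ndarray, mass_fraction: float = 0.2,
                 cap: int = 10) -> np.ndarray:
    """Indices of the smallest score prefix holding >= mass_fraction of the
    total positive relevance mass, in descending score order, capped.

    Ties are broken by index for determinism.  If no score is positive the
    selection is empty (the caller excludes the concept).
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos_total = scores[scores > 0].sum()
    if pos_total <= 0:
        return np.array([], dtype=np.int64)
    order = np.lexsort((np.arange(len(scores)), -scores))
    order = order[scores[order] > 0]
    csum = np.cumsum(scores[order])
    k = int(np.searchsorted(csum, mass_fraction * pos_total - 1e-12) + 1)
    k = max(1, min(k, cap, len(order)))
    return order[:k]


def build_concept(model: LayerGraph, epochs: EpochSet, condition: Condition,
                  *, composite: Composite | None = None,
                  mass_fraction: float = 0.2, cap: int = 10,
                  model_id: str = "model", with_frequency: bool = True
                  ) -> Concept:
    """Score, select and represent one (filter, class) concept."""
    if len(condition.filters) != 1:
        raise ValueError("a concept is built for a single filter")
    ids, scores, rt_all = score_samples(model, epochs, condition, composite,
                                        return_heatmaps=True)
    sel = select_top_k(scores, mass_fraction=mass_fraction, cap=cap)
    f = condition.filters[0]
    if len(sel) == 0:
        logger.info("concept (%s, filter %d, class %d): no positive "
                    "relevance; excluded", model_id, f, condition.class_y)
        map_len = forward_activations(
            model, epochs.data[:1], condition.layer_id).shape[-1]
        return Concept(model_id, condition.layer_id, f, condition.class_y,
                       np.array([], dtype=np.int64), np.array([]),
                       np.zeros(map_len))
    chosen = ids[sel]
    acts = forward_activations(model, epochs.data[chosen], condition.layer_id)
    mean_map = acts[:, f, :].mean(axis=0)
    mean_fr = None
    if with_frequency:
        from .crp import RelevanceTensor

        rt = RelevanceTensor(rt_all.values[sel], domain="time")
        fr = project_time_relevance(epochs.data[chosen], rt, epochs.sfreq)
        mean_fr = FreqRelevance(fr.values.mean(axis=0), fr.freqs)
    return Concept(model_id, condition.layer_id, f, condition.class_y,
                   chosen, scores[sel], mean_map, mean_fr)


def concepts_for_model(model: LayerGraph, epochs: EpochSet, *,
                       layer_id: str = LAST_CONV_LAYER,
                       classes=(0, 1), composite: Composite | None = None,
                       mass_fraction: float = 0.2, cap: int = 10,
                       model_id: str = "model", with_frequency: bool = True
                       ) -> list[Concept]:
    """All (filter, class) concepts of a layer; empty concepts excluded."""
    layer = model[layer_id]
    n_filters = layer.w.shape[0]
    out = []
    for class_y in classes:
        for f in range(n_filters):
            cond = Condition(layer_id=layer_id, filters=(f,), class_y=class_y)
            c = build_concept(model, epochs, cond, composite=composite,
                              mass_fraction=mass_fraction, cap=cap,
                              model_id=model_id, with_frequency=with_frequency)
            if not c.empty:
                out.append(c)
    return out
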
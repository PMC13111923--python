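"""Concept clustering: cosine-metric UMAP embedding + DBSCAN.

Concepts (mean activation maps of filters, one per model x filter x class)
are embedded per class into two dimensions with UMAP under the cosine
metric, then clustered with DBSCAN (eps 0.4, min_samples 15; the density
threshold is scaled down proportionally — floored at 5 — for small concept
sets, since the reference value presumes on the order of 16 models x 16
filters).  The per-model cluster composition quantifies whether a concept
cluster generalizes across models: coverage is the fraction of models
contributing at least one filter to the cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmax import Concept

__all__ = ["ClusterTable", "embed_concepts", "cluster_embedding",
           "effective_min_samples", "cluster_composition", "cluster_concepts"]


@dataclass
class ClusterTable:
    """Per-concept embedding coordinates + labels, and model composition."""

    table: pd.DataFrame  # columns: model, filter, class, x, y, label
    composition: pd.DataFrame  # models x clusters, filter counts
    coverage: pd.Series  # per cluster: fraction of models represented


def embed_concepts(concepts: list[Concept], class_y: int, *, seed: int = 0,
                   n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """2-D cosine-metric UMAP embedding of one class's concept maps."""
    sel = [c for c in concepts if c.class_y == class_y]
    if len(sel) < 3:
        raise ValueError("need at least 3 concepts to embed")
    X = np.stack([c.mean_activation_map for c in sel])
    n_neighbors = min(n_neighbors, len(sel) - 1)
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, metric="cosine",
                            n_neighbors=n_neighbors, min_dist=min_dist,
                            random_state=seed)
        coords = reducer.fit_transform(X)
    return np.asarray(coords, dtype=np.float64)


def effective_min_samples(n_concepts: int, min_samples: int = 15,
                          reference: int = 256, floor: int = 5) -> int:
    """Scale the DBSCAN density threshold down for small concept sets."""
    if n_concepts >= 100:
        return min_samples
    return max(floor, int(round(min_samples * n_concepts / reference)))


def cluster_embedding(coords: np.ndarray, eps: float = 0.4,
                      min_samples: int = 15) -> np.ndarray:
    """DBSCAN labels on the 2-D embedding; -1 marks noise."""
    from sklearn.cluster import DBSCAN

    coords = np.asarray(coords)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite embedding coordinates")
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)


def cluster_composition(labels: np.ndarray, model_ids: list[str]
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Filter counts per (model, cluster) and per-cluster model coverage.

    Noise-labelled concepts (-1) are excluded.
    """
    df = pd.DataFrame({"model": model_ids, "label": labels})
    df = df[df["label"] >= 0]
    comp = (df.groupby(["model", "label"]).size().unstack(fill_value=0)
            .reindex(sorted(set(model_ids)), fill_value=0))
    comp.columns.name = "cluster"
    n_models = len(set(model_ids))
    coverage = (comp > 0).sum(axis=0) / n_models
    return comp, coverage


def cluster_concepts(concepts: list[Concept], class_y: int, *, seed: int = 0,
                     eps: float = 0.4, min_samples: int = 15,
                     scale_min_samples: bool = True,
                     n_neighbors: int = 15, min_dist: float = 0.1
                     ) -> ClusterTable:
    """Embed + cluster one class's concepts and tabulate composition."""
    sel = [c for c in concepts if c.class_y == class_y]
    coords = embed_concepts(concepts, class_y, seed=seed,
                            n_neighbors=n_neighbors, min_dist=min_dist)
    ms = (effective_min_samples(len(sel), min_samples)
          if scale_min_samples else min_samples)
    labels = cluster_embedding(coords, eps=eps, min_samples=ms)
    model_ids = [c.model_id for c in sel]
    table = pd.DataFrame({
        "model": model_ids,
        "filter": [c.filter_id for c in sel],
        "class": class_y,
        "x": coords[:, 0],
        "y": coords[:, 1],
        "label": labels,
    })
    comp, coverage = cluster_composition(labels, model_ids)
    return ClusterTable(table=table, composition=comp, coverage=coverage)
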
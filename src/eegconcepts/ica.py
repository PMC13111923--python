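"""ICA decomposition of cluster data and relevance projection.

The decomposition follows the standard EEG recipe: scale every channel to
unit variance, whiten with PCA (rank-reduced for average-referenced data),
run extended infomax (the variant the ICLabel classifier was trained with),
and rescale so every source has unit variance.  Cluster relevance is
projected through the same linear chain and aggregated per component as the
sum of absolute values, ranking components by how much the classifier
relies on them.  Component labelling (brain / eye / muscle / line noise /
channel noise / heart / other) is delegated to a pluggable labeler: a
ground-truth labeler for synthetic data with known sources, or an adapter
to an external ICLabel implementation when one is installed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import GroundTruth

__all__ = ["ICADecomposition", "fit_ica", "project_relevance",
           "label_components", "GroundTruthLabeler", "ICLabelAdapter"]

logger = logging.getLogger(__name__)

_KIND_TO_LABEL = {"blink": "eye", "line_noise": "line noise",
                  "muscle": "muscle", "signal": "brain"}


@dataclass
class ICADecomposition:
    pre_scale: np.ndarray  # [C] per-channel 1/std factors
    whitening: np.ndarray  # [r, C] PCA whitening matrix (after pre-scale)
    unmixing: np.ndarray  # [r, r] infomax unmixing on whitened data
    source_scale: np.ndarray  # [r] factors normalizing source variance to 1
    mixing: np.ndarray  # [C, r] pseudo-inverse of the full chain
    n_samples: int
    labels: list = field(default_factory=list)  # (label, confidence) pairs

    @property
    def n_components(self) -> int:
        return self.whitening.shape[0]

    @property
    def full_unmixing(self) -> np.ndarray:
        """[r, C]: sources = full_unmixing @ X for raw channel data X."""
        return (self.source_scale[:, None] * self.unmixing
                @ self.whitening * self.pre_scale[None, :])

    def sources(self, X: np.ndarray) -> np.ndarray:
        return self.full_unmixing @ X

    @property
    def topographies(self) -> np.ndarray:
        """Per-component scalp patterns: columns of the mixing matrix."""
        return self.mixing


def _as_matrix(data: np.ndarray) -> np.ndarray:
    """Accept [C, T] or epoched [n, C, T]; concatenate epochs in time."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 3:
        data = np.concatenate(list(data), axis=1)
    return data


def fit_ica(data: np.ndarray, *, n_components: int | None = None,
            rank_tol: float = 1e-10, seed: int = 0) -> ICADecomposition:
    """Fit extended-infomax ICA to cluster data [C, T] (or [n, C, T]).

    Average-referenced data is rank deficient; the PCA step then retains
    ``C - 1`` components (logged).  Source variances are normalized to 1.
    """
    from mne.preprocessing import infomax

    X = _as_matrix(data)
    C, T = X.shape
    if T < 4 * C:
        raise ValueError("need substantially more time points than channels")
    X = X - X.mean(axis=1, keepdims=True)
    std = X.std(axis=1)
    pre_scale = 1.0 / np.maximum(std, 1e-30)
    Xs = X * pre_scale[:, None]
    cov = (Xs @ Xs.T) / T
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > rank_tol * evals[0]).sum())
    if n_components is None:
        n_components = rank
    if n_components < rank:
        logger.info("retaining %d of %d non-degenerate components",
                    n_components, rank)
    elif rank < C:
        logger.info("rank-deficient data: retaining %d of %d components",
                    rank, C)
    r = min(n_components, rank)
    whitening = (evecs[:, :r] / np.sqrt(evals[:r])).T  # [r, C]
    Z = whitening @ Xs
    W = infomax(Z.T, extended=True, random_state=seed, verbose="error")
    S = W @ Z
    src_std = S.std(axis=1)
    source_scale = 1.0 / np.maximum(src_std, 1e-30)
    ica = ICADecomposition(pre_scale=pre_scale, whitening=whitening,
                           unmixing=W, source_scale=source_scale,
                           mixing=np.zeros((C, r)), n_samples=T)
    ica.mixing = np.linalg.pinv(ica.full_unmixing)
    return ica


def project_relevance(ica: ICADecomposition, relevance: np.ndarray
                      ) -> np.ndarray:
    """Per-component relevance: |unmixing chain applied to R| summed in time.

    ``relevance`` is co-shaped with the cluster data ([C, T] or [n, C, T]).
    The projection itself is linear; the absolute value is taken afterwards,
    so the ranking is invariant to component sign flips.
    """
    R = _as_matrix(relevance)
    if R.shape[0] != ica.full_unmixing.shape[1]:
        raise ValueError("relevance channel count does not match the "
                         "decomposition")
    return np.abs(ica.full_unmixing @ R).sum(axis=1)


class GroundTruthLabeler:
    """Oracle labeler for synthetic cohorts with known planted sources.

    Matches each component topography against the planted loading vectors by
    absolute correlation; below ``threshold`` the component is 'other'.
    """

    def __init__(self, truth: GroundTruth, threshold: float = 0.6):
        self.truth = truth
        self.threshold = threshold

    def __call__(self, ica: ICADecomposition) -> list[tuple[str, float]]:
        out = []
        for topo in ica.topographies.T:
            best_kind, best_corr = "other", 0.0
            for src in self.truth.sources:
                loading = src.loading - src.loading.mean()
                t = topo - topo.mean()
                denom = np.linalg.norm(loading) * np.linalg.norm(t)
                if denom == 0:
                    continue
                corr = abs(float(loading @ t) / denom)
                if corr > best_corr:
                    best_kind, best_corr = src.kind, corr
            if best_corr < self.threshold:
                out.append(("other", best_corr))
            else:
                out.append((_KIND_TO_LABEL.get(best_kind, "other"), best_corr))
        return out


class ICLabelAdapter:
    """Adapter to an external ICLabel implementation (optional dependency).

    The external classifier is treated as an off-the-shelf component; when
    it is unavailable every component is labelled 'unlabelled' and the
    pipeline continues.
    """

    def __init__(self, epochs=None):
        self.epochs = epochs

    def __call__(self, ica: ICADecomposition) -> list[tuple[str, float]]:
        try:
            import mne_icalabel  # noqa: F401
        except ImportError:
            logger.warning("mne-icalabel not installed; components left "
                           "unlabelled")
            return [("unlabelled", 0.0)] * ica.n_components
        raise NotImplementedError(
            "wire this adapter to mne_icalabel.label_components with an "
            "mne.preprocessing.ICA instance built from the decomposition")


def label_components(ica: ICADecomposition, labeler=None
                     ) -> list[tuple[str, float]]:
    """Attach one (label, confidence) pair per component.

    With ``labeler=None`` (or a failing labeler) components are labelled
    'unlabelled' and the pipeline continues.
    """
    if labeler is None:
        labels = [("unlabelled", 0.0)] * ica.n_components
    else:
        try:
            labels = labeler(ica)
        except Exception as exc:  # labeler unavailable/broken: degrade
            logger.warning("labeler failed (%s); components left unlabelled",
                           exc)
            labels = [("unlabelled", 0.0)] * ica.n_components
    if len(labels) != ica.n_components:
        raise ValueError("labeler returned wrong number of labels")
    ica.labels = labels
    return labels
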
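"""Virtual inspection layer: relevance in the frequency domain.

The VIL expresses each input epoch through the invertible pair
``x -> rFFT(x) -> irFFT -> x``: a real-valued parameterization (real and
imaginary coordinate per frequency bin) followed by the inverse transform,
inserted before the network's input layer.  The inverse DFT is a bias-free
linear map, so input-space relevance can be propagated one step further
with the ε-rule, yielding relevance per frequency bin without retraining.
Per-bin relevance is the sum of the relevance of the bin's real and
imaginary coordinates; totals are conserved because the transform is a
linear bijection.

The frequency grid is fixed by the epoch length (1/3 Hz for 3-s windows at
128 Hz; no zero-padding).  The one-sided spectrum's doubling of interior
bins is carried by the linear map itself, so no manual correction of the
relevance is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crp import Composite, Condition, RelevanceTensor, crp, lrp
from .nn.model import LayerGraph

__all__ = ["FreqRelevance", "BandScheme", "VILModel", "attach_vil",
           "relevance_in_frequency", "band_aggregate"]


@dataclass
class FreqRelevance:
    """Relevance per (channel, frequency bin): values [..., C, n_bins]."""

    values: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        if self.values.shape[-1] != len(self.freqs):
            raise ValueError("values last axis must match freqs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite frequency relevance")

    domain = "frequency"

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def mean_over_samples(self) -> "FreqRelevance":
        if self.values.ndim == 2:
            return self
        return FreqRelevance(self.values.mean(axis=0), self.freqs)


@dataclass(frozen=True)
class BandScheme:
    """Named, ordered, non-overlapping half-open frequency bands [lo, hi)."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 0.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 12.0, 30.0),
        ("gamma", 30.0, 60.0),
    )

    def __post_init__(self):
        prev_hi = -np.inf
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name}: lo must be < hi")
            if lo < prev_hi:
                raise ValueError("bands must be ordered and non-overlapping")
            prev_hi = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def bin_assignment(self, freqs: np.ndarray) -> np.ndarray:
        """Band index per bin; -1 for bins outside every band."""
        out = np.full(len(freqs), -1, dtype=np.int64)
        for i, (_, lo, hi) in enumerate(self.bands):
            out[(freqs >= lo) & (freqs < hi)] = i
        return out


class VILModel:
    """A model with the DFT/inverse-DFT pair prepended to its input."""

    def __init__(self, model: LayerGraph):
        self.model = model
        self.n_times = model.n_times

    def spectrum(self, x) -> np.ndarray:
        """Complex one-sided spectrum of epochs [..., C, T]."""
        return np.fft.rfft(np.asarray(x, dtype=np.float64), axis=-1)

    def freqs(self, sfreq: float) -> np.ndarray:
        return np.fft.rfftfreq(self.n_times, d=1.0 / sfreq)

    def reconstruct(self, spectrum) -> np.ndarray:
        return np.fft.irfft(spectrum, n=self.n_times, axis=-1)

    def forward(self, x):
        """Forward pass routed through the DFT pair (identity composition)."""
        return self.model.forward(self.reconstruct(self.spectrum(x)))


def attach_vil(model: LayerGraph) -> VILModel:
    return VILModel(model)


def _bin_weights(n_times: int) -> np.ndarray:
    n_bins = n_times // 2 + 1
    w = np.full(n_bins, 2.0)
    w[0] = 1.0
    if n_times % 2 == 0:
        w[-1] = 1.0
    return w


def relevance_in_frequency(vil: VILModel, x, sfreq: float,
                           condition: Condition | None = None,
                           class_y: int | None = None,
                           composite: Composite | None = None,
                           eps: float = 1e-9) -> FreqRelevance:
    """Propagate relevance through the inverse DFT into frequency bins.

    With ``condition`` the heatmap is the CRP heatmap for that condition;
    otherwise the unconditioned LRP heatmap for ``class_y``.  The total is
    conserved: summed frequency relevance equals summed time relevance up to
    the ε stabilization.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if condition is not None:
        rt = crp(vil.model, x, condition, composite)
    else:
        if class_y is None:
            raise ValueError("either condition or class_y is required")
        rt = lrp(vil.model, x, class_y, composite)
    return project_time_relevance(x, rt, sfreq, eps=eps)


def project_time_relevance(x: np.ndarray, rt: RelevanceTensor, sfreq: float,
                           eps: float = 1e-9) -> FreqRelevance:
    """ε-rule step through the inverse DFT for a precomputed time heatmap."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    R = rt.values if rt.values.ndim == 3 else rt.values[None]
    T = x.shape[-1]
    scale = np.abs(x).mean(axis=(-2, -1), keepdims=True)
    stab = eps * np.maximum(scale, 1e-30)
    s = R / (x + np.where(x >= 0, 1.0, -1.0) * stab)
    spec_x = np.fft.rfft(x, axis=-1)
    spec_s = np.fft.rfft(s, axis=-1)
    w = _bin_weights(T) / T
    r_re = spec_x.real * w * spec_s.real
    r_im = spec_x.imag * w * spec_s.imag
    freqs = np.fft.rfftfreq(T, d=1.0 / sfreq)
    return FreqRelevance(values=r_re + r_im, freqs=freqs)


def band_aggregate(fr: FreqRelevance, bands: BandScheme | None = None,
                   positive_only: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sum bin relevance into bands: values [..., C, n_bands].

    Returns ``(band_values, unassigned)`` where ``unassigned`` is the mass
    of bins outside every band (e.g. at/above the top band edge).  With
    ``positive_only`` negative bin values are dropped before summing, per
    the positive-evidence display convention.
    """
    bands = bands or BandScheme()
    vals = np.maximum(fr.values, 0.0) if positive_only else fr.values
    assign = bands.bin_assignment(fr.freqs)
    out = np.zeros(vals.shape[:-1] + (len(bands.bands),), dtype=vals.dtype)
    for i in range(len(bands.bands)):
        out[..., i] = vals[..., assign == i].sum(axis=-1)
    unassigned = vals[..., assign == -1].sum(axis=-1)
    return out, unassigned
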
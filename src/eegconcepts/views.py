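"""Neuroscientific views of cluster relevance: PSD curves, band topographies,
functional grouping.

A cluster of concepts is summarized by (a) the power spectral density of its
representative samples next to the relevance share per frequency bin, (b)
per-band topographic data (band power scaled by the band's cross-channel
average to undo the 1/f dominance — relevance left unscaled, positive part
only), and (c) a region x band matrix of mean positive relevance over
anatomically motivated channel groups (left/right frontal, temporal,
occipital; the temporal groups include FC5, C5, CP5 / FC6, C6, CP6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmax import Concept
from .synthetic import EpochSet
from .vil import BandScheme, FreqRelevance, band_aggregate

__all__ = ["RegionMap", "BandTopoData", "DEFAULT_REGIONS", "channel_positions",
           "cluster_samples", "cluster_mean_freq_relevance",
           "psd_relevance_curves", "band_topo", "functional_grouping"]


@dataclass(frozen=True)
class RegionMap:
    """Disjoint named channel groups."""

    regions: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        seen = set()
        for name, chans in self.regions:
            if not chans:
                raise ValueError(f"region {name!r} is empty")
            for ch in chans:
                if ch in seen:
                    raise ValueError(f"channel {ch!r} in multiple regions")
                seen.add(ch)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.regions)

    def channels(self, name: str) -> tuple[str, ...]:
        for rname, chans in self.regions:
            if rname == name:
                return chans
        raise KeyError(name)

    def validate_montage(self, montage) -> None:
        for name, chans in self.regions:
            for ch in chans:
                if ch not in montage:
                    raise ValueError(
                        f"region {name!r} channel {ch!r} not in montage")


DEFAULT_REGIONS = RegionMap((
    ("frontal_left", ("Fp1", "F7", "F3")),
    ("frontal_right", ("Fp2", "F8", "F4")),
    ("temporal_left", ("FC5", "C5", "CP5", "T7")),
    ("temporal_right", ("FC6", "C6", "CP6", "T8")),
    ("occipital_left", ("O1", "PO3", "P7")),
    ("occipital_right", ("O2", "PO4", "P8")),
))


@dataclass
class BandTopoData:
    """Per-band channel vectors of scaled power and positive relevance."""

    bands: BandScheme
    channels: tuple[str, ...]
    positions: np.ndarray  # [n_channels, 2]
    scaled_power: np.ndarray  # [n_bands, n_channels], >= 0
    relevance: np.ndarray  # [n_bands, n_channels], >= 0
    extras: dict = field(default_factory=dict)


def channel_positions(channels) -> np.ndarray:
    """2-D head-plane positions for standard 10-20/10-10 channel names."""
    import mne

    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            montage = mne.channels.make_standard_montage("standard_1020")
    pos3d = montage.get_positions()["ch_pos"]
    out = np.zeros((len(channels), 2))
    for i, ch in enumerate(channels):
        if ch not in pos3d:
            raise ValueError(f"no standard position for channel {ch!r}")
        out[i] = pos3d[ch][:2]
    return out


def cluster_samples(concepts: list[Concept], epochs: EpochSet) -> np.ndarray:
    """Concatenated representative epochs of a cluster [n, C, T].

    A sample selected by several concepts appears once per selection, so the
    aggregate weights samples by how many concepts they represent.
    """
    ids = np.concatenate([c.sample_ids for c in concepts if not c.empty])
    return epochs.data[ids]


def cluster_mean_freq_relevance(concepts: list[Concept]) -> FreqRelevance:
    """Mean frequency-domain relevance over a cluster's concepts."""
    frs = [c.mean_freq_relevance for c in concepts
           if c.mean_freq_relevance is not None]
    if not frs:
        raise ValueError("concepts carry no frequency relevance")
    return FreqRelevance(np.mean([fr.values for fr in frs], axis=0),
                         frs[0].freqs)


def _psd(samples: np.ndarray, sfreq: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean periodogram over samples on the epoch's rFFT grid."""
    from scipy.signal import periodogram

    freqs, p = periodogram(samples, fs=sfreq, axis=-1,
                           window="boxcar", detrend=False)
    return freqs, p.mean(axis=0)  # [C, n_bins]


def psd_relevance_curves(concepts: list[Concept], epochs: EpochSet,
                         f_max: float = 45.0) -> pd.DataFrame:
    """Channel-averaged PSD next to the relevance share per frequency bin.

    The relevance share is the positive bin relevance as a percentage of the
    total positive relevance (all bins), so the full-spectrum shares sum to
    100; the rows above ``f_max`` carry the reported remainder.
    """
    if not concepts:
        raise ValueError("empty cluster")
    samples = cluster_samples(concepts, epochs)
    freqs, psd = _psd(samples, epochs.sfreq)
    fr = cluster_mean_freq_relevance(concepts)
    pos = np.maximum(fr.values, 0.0).sum(axis=0)  # over channels -> per bin
    total = pos.sum()
    share = 100.0 * pos / total if total > 0 else np.zeros_like(pos)
    df = pd.DataFrame({
        "freq_hz": freqs,
        "psd": psd.mean(axis=0),
        "relevance_pct": share,
    })
    df.attrs["pct_above_fmax"] = float(share[freqs > f_max].sum())
    df.attrs["f_max"] = f_max
    return df


def band_topo(concepts: list[Concept], epochs: EpochSet,
              bands: BandScheme | None = None) -> BandTopoData:
    """Topographic band data: power scaled per band, relevance unscaled.

    Band power per channel is divided by the band's cross-channel average
    (counteracting the 1/f power law across bands); the relevance vectors
    are the positive-only band aggregates of the cluster's frequency
    relevance, deliberately left unscaled.
    """
    bands = bands or BandScheme()
    positions = channel_positions(epochs.channels)
    samples = cluster_samples(concepts, epochs)
    freqs, psd = _psd(samples, epochs.sfreq)  # [C, n_bins]
    assign = bands.bin_assignment(freqs)
    n_bands = len(bands.bands)
    power = np.zeros((n_bands, psd.shape[0]))
    for i in range(n_bands):
        power[i] = psd[:, assign == i].sum(axis=1)
    mean_power = power.mean(axis=1, keepdims=True)
    scaled = power / np.maximum(mean_power, 1e-30)
    fr = cluster_mean_freq_relevance(concepts)
    rel, _ = band_aggregate(fr, bands, positive_only=True)  # [C, n_bands]
    return BandTopoData(bands=bands, channels=epochs.channels,
                        positions=positions, scaled_power=scaled,
                        relevance=rel.T.copy())


def functional_grouping(fr: FreqRelevance, channels, regions: RegionMap,
                        bands: BandScheme | None = None,
                        absolute: bool = False) -> pd.DataFrame:
    """Region x band matrix of mean positive relevance.

    Negative relevance is discarded (clipped to zero but kept in the mean's
    denominator) before averaging over the region's channels and the band's
    bins; ``absolute=True`` switches to the mean of absolute values.
    """
    bands = bands or BandScheme()
    regions.validate_montage(channels)
    vals = np.abs(fr.values) if absolute else np.maximum(fr.values, 0.0)
    assign = bands.bin_assignment(fr.freqs)
    ch_index = {c: i for i, c in enumerate(channels)}
    out = np.zeros((len(regions.names), len(bands.bands)))
    for i, rname in enumerate(regions.names):
        rows = [ch_index[c] for c in regions.channels(rname)]
        for j in range(len(bands.bands)):
            cell = vals[np.ix_(rows, np.flatnonzero(assign == j))]
            out[i, j] = cell.mean() if cell.size else 0.0
    return pd.DataFrame(out, index=list(regions.names),
                        columns=list(bands.names))
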
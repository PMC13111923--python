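"""Preprocessing chain: notch, bandpass, resample, window, CAR, standardize.

The chain mirrors common subject-independent EEG pipelines: 50 Hz notch,
1-60 Hz bandpass, resampling to 128 Hz, non-overlapping 3-s windows, common
average reference, and per-channel standardization in consecutive batches of
128 epochs (emulating an online system that can only normalize with the
statistics of the data seen so far in a block).

Filtering and resampling are delegated to :mod:`mne.filter` (zero-phase IIR
notch, FIR bandpass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import EpochSet

__all__ = [
    "PreprocConfig",
    "filter_and_resample",
    "make_windows",
    "common_average_reference",
    "batch_standardize",
    "preprocess_epochs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocConfig:
    notch_hz: float = 50.0
    band: tuple[float, float] = (1.0, 60.0)
    resample_hz: float = 128.0
    window_s: float = 3.0
    batch_size: int = 128

    def validate(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise ValueError("band must satisfy lo < hi")
        if hi >= self.resample_hz / 2.0:
            raise ValueError(
                f"band high edge {hi} Hz must be below the post-resampling "
                f"Nyquist frequency {self.resample_hz / 2.0} Hz")
        n = self.window_s * self.resample_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_s * resample_hz must be an integer")


def filter_and_resample(raw: np.ndarray, sfreq: float,
                        cfg: PreprocConfig = PreprocConfig()) -> np.ndarray:
    """Notch, bandpass and resample continuous EEG [n_channels, n_times].

    Returns data at ``cfg.resample_hz``.  Requires ``sfreq > 2 * band_hi``.
    """
    import mne.filter

    cfg.validate()
    if sfreq <= 2 * cfg.band[1]:
        raise ValueError("input sampling rate must exceed twice the band high edge")
    x = np.ascontiguousarray(raw, dtype=np.float64)
    x = mne.filter.notch_filter(x, sfreq, freqs=cfg.notch_hz, method="iir",
                                verbose="error")
    x = mne.filter.filter_data(x, sfreq, cfg.band[0], cfg.band[1],
                               verbose="error")
    if sfreq != cfg.resample_hz:
        x = mne.filter.resample(x, up=cfg.resample_hz, down=sfreq,
                                verbose="error")
    return x


def make_windows(cont: np.ndarray, sfreq: float, window_s: float = 3.0,
                 labels=None, subject: int = 0,
                 channels=None) -> EpochSet:
    """Cut continuous data into non-overlapping, left-aligned windows.

    Windows are half-open sample intervals ``[i*n, (i+1)*n)``; a trailing
    remainder shorter than one window is dropped.
    """
    n = int(round(sfreq * window_s))
    n_win = cont.shape[-1] // n
    data = cont[:, : n_win * n].reshape(cont.shape[0], n_win, n)
    data = np.moveaxis(data, 0, 1)  # [n_win, n_channels, n]
    if labels is None:
        labels = np.zeros(n_win, dtype=np.int64)
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(cont.shape[0]))
    return EpochSet(data, np.asarray(labels),
                    np.full(n_win, subject, dtype=np.int64),
                    tuple(channels), sfreq)


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels from every channel."""
    if epochs.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    out = epochs.copy()
    out.data -= out.data.mean(axis=1, keepdims=True)
    return out


def batch_standardize(epochs: EpochSet, batch_size: int = 128,
                      std_floor: float = 1e-8) -> EpochSet:
    """Standardize per channel within consecutive batches of epochs.

    For each batch of ``batch_size`` consecutive epochs (in the order given,
    which is taken to be acquisition order), each channel is centered and
    scaled by the mean/std over the batch's pooled time points.  The final
    partial batch uses its own statistics.  Zero-variance channels are
    guarded by ``std_floor`` and logged.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out = epochs.copy()
    for start in range(0, out.n_epochs, batch_size):
        block = out.data[start:start + batch_size]
        mean = block.mean(axis=(0, 2), keepdims=True)
        std = block.std(axis=(0, 2), keepdims=True)
        n_degenerate = int((std < std_floor).sum())
        if n_degenerate:
            logger.warning("batch at epoch %d: %d zero-variance channel(s), "
                           "std floored at %g", start, n_degenerate, std_floor)
        std = np.maximum(std, std_floor)
        out.data[start:start + batch_size] = (block - mean) / std
    return out


def preprocess_epochs(epochs: EpochSet, batch_size: int = 128,
                      per_subject: bool = True) -> EpochSet:
    """CAR then batch standardization, the epoch-level tail of the chain.

    With ``per_subject`` (default) standardization batches never cross
    subject boundaries, so leave-one-subject-out folds share no statistics.
    """
    out = common_average_reference(epochs)
    if per_subject:
        parts = []
        order = []
        for s in np.unique(out.subjects):
            mask = out.subjects == s
            parts.append(batch_standardize(out.select(mask), batch_size))
            order.append(np.flatnonzero(mask))
        data = np.empty_like(out.data)
        for idx, part in zip(order, parts):
            data[idx] = part.data
        out = EpochSet(data, out.labels, out.subjects, out.channels, out.sfreq)
    else:
        out = batch_standardize(out, batch_size)
    return out
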
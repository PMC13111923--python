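"""Synthetic multi-subject EEG cohorts with known ground truth.

Generates epoched binary-class EEG in which the class-discriminative signal
(band-limited oscillations on chosen channels), the background (1/f "pink"
noise) and the artifact sources (eye blinks, 50 Hz line noise, muscle bursts)
are all planted explicitly, so every downstream stage — training, relevance
propagation, frequency attribution, clustering, ICA — can be validated
against a known answer.

The construction is a linear source model: each epoch is the sum of
``loading (n_channels,) x time_course (n_times,)`` terms plus channel-wise
pink noise.  :func:`ground_truth` returns exactly those loadings and time
courses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_MONTAGE",
    "STUDY_MONTAGE",
    "SignalSpec",
    "ArtifactSpec",
    "CohortConfig",
    "EpochSet",
    "Source",
    "GroundTruth",
    "generate_cohort",
    "ground_truth",
    "lateralized_cohort_config",
    "two_concept_cohort_config",
]

#: Compact 20-channel montage used by the study cohorts: every channel of
#: the default functional-grouping regions (frontal / temporal / occipital,
#: left and right) plus F3/F4.  Keeps the scaled-down leave-one-out studies
#: a desk-scale computation.
STUDY_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "F4", "F8", "FC5", "FC6",
    "C5", "C6", "CP5", "CP6", "T7", "T8",
    "P7", "P8", "O1", "O2", "PO3", "PO4",
)

#: 32 standard 10-20/10-10 channel names.  Includes the channels the default
#: functional-grouping regions need (FC5, C5, CP5 / FC6, C6, CP6 for the
#: temporal lobes) so topographic and region operations work out of the box.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "C5", "C3", "Cz", "C4", "C6",
    "T7", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2", "PO3", "PO4",
)


class ConfigurationError(ValueError):
    """Raised for inconsistent cohort configurations."""


@dataclass(frozen=True)
class SignalSpec:
    """One class-conditional band-power signature.

    Parameters
    ----------
    band_center, bandwidth
        Center frequency and width (Hz) of the planted oscillation.  The
        per-epoch carrier frequency is drawn uniformly from the band.
    channels
        Channel names carrying the signature (the spatial loading is 1 on
        these channels, 0 elsewhere).
    amplitude
        Peak amplitude in µV.
    envelope
        ``"flat"`` for a stationary oscillation, or ``("gaussian", center,
        width)`` with center/width as fractions of the epoch length for an
        event-locked band-power burst (ERD/ERS-like).
    """

    band_center: float
    bandwidth: float
    channels: tuple[str, ...]
    amplitude: float
    envelope: tuple | str = "flat"
    #: which epochs of the class express the signature: "all", or one of
    #: two alternating within-class trial types ("half_a" / "half_b").
    #: Splitting a class into trial types that each express only one
    #: signature forces classifiers to learn *both* concepts.
    presence: str = "all"
    #: sources sharing a gain_group share one per-epoch amplitude gain
    #: (see CohortConfig.epoch_gain_jitter); sources in different groups
    #: draw independent gains, so no single signature is reliable alone
    gain_group: str = "default"


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact source: kind in {'blink', 'line_noise', 'muscle'}."""

    kind: str
    channels: tuple[str, ...]
    rate_or_freq: float  # blinks: events/s; line_noise: Hz; muscle: bursts/s
    amplitude: float


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 6
    n_epochs_per_class: int = 20
    sfreq: float = 128.0
    epoch_len: float = 3.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    signal_spec: tuple[tuple[int, SignalSpec], ...] = ()  # (class, spec)
    noise_spec: tuple[float, float] = (1.0, 10.0)  # (pink exponent, std µV)
    artifact_spec: tuple[ArtifactSpec, ...] = ()
    subject_variability: tuple[float, float] = (0.2, 0.5)  # amp frac, Hz
    #: one shared multiplicative gain per epoch applied to every signal
    #: source (uniform in 1 +- this fraction).  Emulates global rhythm
    #: strength varying with arousal; with a contralateral-contrast design
    #: it makes single-hemisphere power ambiguous between classes while the
    #: left/right contrast stays informative.
    epoch_gain_jitter: float = 0.0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.montage)

    @property
    def n_times(self) -> int:
        n = self.sfreq * self.epoch_len
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("sfreq * epoch_len must be an integer")
        return int(round(n))

    def validate(self) -> None:
        if len(set(self.montage)) != len(self.montage):
            raise ConfigurationError("montage channel names must be unique")
        self.n_times  # noqa: B018 - raises if non-integer
        for _, spec in self.signal_spec:
            if spec.amplitude < 0:
                raise ConfigurationError("signal amplitude must be >= 0")
            if spec.presence not in ("all", "half_a", "half_b"):
                raise ConfigurationError(
                    f"unknown presence {spec.presence!r}")
            for ch in spec.channels:
                if ch not in self.montage:
                    raise ConfigurationError(f"unknown channel {ch!r} in signal_spec")
        for art in self.artifact_spec:
            if art.amplitude < 0:
                raise ConfigurationError("artifact amplitude must be >= 0")
            if art.kind not in ("blink", "line_noise", "muscle"):
                raise ConfigurationError(f"unknown artifact kind {art.kind!r}")
            for ch in art.channels:
                if ch not in self.montage:
                    raise ConfigurationError(f"unknown channel {ch!r} in artifact_spec")
        if self.noise_spec[1] < 0:
            raise ConfigurationError("noise amplitude must be >= 0")


@dataclass
class EpochSet:
    """Epoched EEG: ``data`` [n_epochs, n_channels, n_times] in µV."""

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    channels: tuple[str, ...]
    sfreq: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        n, c, _ = self.data.shape
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("labels/subjects length must match n_epochs")
        if len(self.channels) != c:
            raise ValueError("channels length must match data axis 1")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.labels[mask],
                        self.subjects[mask], self.channels, self.sfreq)

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.labels.copy(),
                        self.subjects.copy(), self.channels, self.sfreq)


@dataclass
class Source:
    """One planted source: spatial loading plus per-epoch time courses."""

    name: str
    kind: str  # 'signal' | 'blink' | 'line_noise' | 'muscle'
    class_y: int | None  # class for signal sources, None for artifacts
    loading: np.ndarray  # [n_channels]
    time_courses: np.ndarray  # [n_epochs, n_times]


@dataclass
class GroundTruth:
    sources: list[Source]
    noise: np.ndarray  # [n_epochs, n_channels, n_times]

    def reconstruct(self) -> np.ndarray:
        out = self.noise.copy()
        for s in self.sources:
            out += s.loading[None, :, None] * s.time_courses[:, None, :]
        return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                exponent: float, std: float, sfreq: float,
                band: tuple[float, float] = (1.0, 60.0)) -> np.ndarray:
    """1/f^exponent Gaussian noise along the last axis, scaled to ``std``.

    The spectrum is restricted to ``band`` (default 1-60 Hz): the generator
    emulates data that has already passed the preprocessing bandpass, so no
    power is planted where the analysis chain would have removed it.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    scale[inside] = freqs[inside] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),)))
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    cur = x.std()
    if cur > 0:
        x *= std / cur
    return x


def _blink_kernel(sfreq: float) -> np.ndarray:
    """Stereotyped biphasic blink pulse (~400 ms)."""
    t = np.arange(int(0.4 * sfreq)) / sfreq
    main = np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)
    rebound = -0.3 * np.exp(-0.5 * ((t - 0.28) / 0.08) ** 2)
    return main + rebound


def _envelope(spec_env, n_times: int) -> np.ndarray:
    if isinstance(spec_env, str) and spec_env == "flat":
        return np.ones(n_times)
    kind, center, width = spec_env
    if kind != "gaussian":
        raise ConfigurationError(f"unknown envelope kind {kind!r}")
    t = np.arange(n_times) / n_times
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _synthesize(config: CohortConfig) -> tuple[EpochSet, GroundTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t = config.n_times
    n_ch = config.n_channels
    ch_index = {c: i for i, c in enumerate(config.montage)}
    n_epochs_total = config.n_subjects * 2 * config.n_epochs_per_class

    labels = np.zeros(n_epochs_total, dtype=np.int64)
    subjects = np.zeros(n_epochs_total, dtype=np.int64)
    epoch_in_class = np.zeros(n_epochs_total, dtype=np.int64)
    idx = 0
    for s in range(config.n_subjects):
        for y in (0, 1):
            for e in range(config.n_epochs_per_class):
                labels[idx] = y
                subjects[idx] = s
                epoch_in_class[idx] = e
                idx += 1

    amp_jit, freq_jit = config.subject_variability
    gain_jit = config.epoch_gain_jitter
    gain_groups = []
    for _, spec in config.signal_spec:
        if spec.gain_group not in gain_groups:
            gain_groups.append(spec.gain_group)
    if gain_jit > 0:
        epoch_gain = 1.0 + rng.uniform(
            -gain_jit, gain_jit, size=(n_epochs_total, max(len(gain_groups), 1)))
    else:
        epoch_gain = np.ones((n_epochs_total, max(len(gain_groups), 1)))
    # one jitter draw per (subject, source), fixed for that subject
    n_signal = len(config.signal_spec)
    n_art = len(config.artifact_spec)
    subj_amp = 1.0 + rng.uniform(-amp_jit, amp_jit,
                                 size=(config.n_subjects, n_signal + n_art))
    subj_freq = rng.normal(0.0, freq_jit, size=(config.n_subjects, n_signal))

    t = np.arange(n_t) / config.sfreq
    sources: list[Source] = []

    for i_sig, (class_y, spec) in enumerate(config.signal_spec):
        loading = np.zeros(n_ch)
        for ch in spec.channels:
            loading[ch_index[ch]] = 1.0
        env = _envelope(spec.envelope, n_t)
        courses = np.zeros((n_epochs_total, n_t))
        for e in range(n_epochs_total):
            if labels[e] != class_y:
                continue
            if spec.presence == "half_a" and epoch_in_class[e] % 2 != 0:
                continue
            if spec.presence == "half_b" and epoch_in_class[e] % 2 != 1:
                continue
            s = subjects[e]
            f = (spec.band_center + subj_freq[s, i_sig]
                 + rng.uniform(-0.5, 0.5) * spec.bandwidth)
            phase = rng.uniform(0, 2 * np.pi)
            amp = (spec.amplitude * subj_amp[s, i_sig]
                   * epoch_gain[e, gain_groups.index(spec.gain_group)])
            courses[e] = amp * env * np.sin(2 * np.pi * f * t + phase)
        sources.append(Source(
            name=f"signal_c{class_y}_{spec.band_center:g}Hz",
            kind="signal", class_y=class_y, loading=loading,
            time_courses=courses))

    blink = _blink_kernel(config.sfreq)
    for i_art, art in enumerate(config.artifact_spec):
        loading = np.zeros(n_ch)
        for ch in art.channels:
            loading[ch_index[ch]] = 1.0
        courses = np.zeros((n_epochs_total, n_t))
        for e in range(n_epochs_total):
            s = subjects[e]
            amp = art.amplitude * subj_amp[s, n_signal + i_art]
            if art.kind == "blink":
                n_events = rng.poisson(art.rate_or_freq * config.epoch_len)
                for _ in range(n_events):
                    onset = rng.integers(0, max(1, n_t - len(blink)))
                    courses[e, onset:onset + len(blink)] += amp * blink[: n_t - onset]
            elif art.kind == "line_noise":
                phase = rng.uniform(0, 2 * np.pi)
                courses[e] = amp * np.sin(2 * np.pi * art.rate_or_freq * t + phase)
            elif art.kind == "muscle":
                n_events = rng.poisson(art.rate_or_freq * config.epoch_len)
                burst_len = int(0.3 * config.sfreq)
                for _ in range(n_events):
                    onset = rng.integers(0, max(1, n_t - burst_len))
                    noise = rng.standard_normal(min(burst_len, n_t - onset))
                    courses[e, onset:onset + len(noise)] += amp * noise
        courses_label = {"blink": "blink", "line_noise": "line", "muscle": "muscle"}
        sources.append(Source(
            name=f"{courses_label[art.kind]}_{i_art}",
            kind=art.kind, class_y=None, loading=loading,
            time_courses=courses))

    exponent, noise_std = config.noise_spec
    if noise_std > 0:
        noise = _pink_noise(rng, (n_epochs_total, n_ch, n_t),
                            exponent, noise_std, config.sfreq)
    else:
        noise = np.zeros((n_epochs_total, n_ch, n_t))

    gt = GroundTruth(sources=sources, noise=noise)
    epochs = EpochSet(gt.reconstruct(), labels, subjects,
                      config.montage, config.sfreq)
    return epochs, gt


def generate_cohort(config: CohortConfig) -> EpochSet:
    """Generate the cohort.  Deterministic given ``config.seed``."""
    epochs, _ = _synthesize(config)
    return epochs


def ground_truth(config: CohortConfig) -> GroundTruth:
    """Planted sources (loadings + time courses) and the noise floor.

    ``ground_truth(cfg).reconstruct()`` equals ``generate_cohort(cfg).data``
    exactly, because both calls replay the same seeded stream.
    """
    _, gt = _synthesize(config)
    return gt


def lateralized_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study cohort: left-vs-right 10 Hz (alpha) lateralization.

    Class 0 carries a 10 Hz oscillation over the left temporal electrodes,
    class 1 over the right, emulating lateralized paradigms (auditory
    attention, motor imagery).  Eye blinks and 50 Hz line noise are planted
    class-independently so explanations can be checked against them.
    """
    montage = tuple(overrides.pop("montage", STUDY_MONTAGE))
    left = ("FC5", "C5", "CP5", "T7")
    right = ("FC6", "C6", "CP6", "T8")
    # bilateral rhythm with contralateral contrast (ERD-like): both classes
    # carry the 10 Hz rhythm on both sides; the class difference is which
    # hemisphere expresses it strongly
    cfg = CohortConfig(
        n_epochs_per_class=24,
        montage=montage,
        signal_spec=(
            (0, SignalSpec(10.0, 2.0, left, 9.0)),
            (0, SignalSpec(10.0, 2.0, right, 4.5)),
            (1, SignalSpec(10.0, 2.0, left, 4.5)),
            (1, SignalSpec(10.0, 2.0, right, 9.0)),
        ),
        epoch_gain_jitter=0.5,
        noise_spec=(1.0, 10.0),
        artifact_spec=(
            ArtifactSpec("blink",
                         tuple(c for c in ("Fp1", "Fp2", "F7", "F8")
                               if c in montage), 0.25, 60.0),
            ArtifactSpec("line_noise", montage, 50.0, 1.0),
        ),
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def two_concept_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Cohort with two planted concept types per class (band x hemisphere).

    Each class carries two signatures that differ in band, scalp site and
    within-epoch envelope: an early 10 Hz temporal burst and a late 22 Hz
    occipital burst, mirrored between hemispheres across classes.  Filters
    tuning to one or the other produce distinct activation-map concepts, so
    concept clustering should recover two groups per class.
    """
    montage = tuple(overrides.pop("montage", STUDY_MONTAGE))
    tl, tr = ("FC5", "C5", "CP5", "T7"), ("FC6", "C6", "CP6", "T8")
    ol, orr = ("O1", "PO3", "P7"), ("O2", "PO4", "P8")
    early = ("gaussian", 0.25, 0.15)
    late = ("gaussian", 0.75, 0.15)
    # every trial of a class carries both signatures (early 10 Hz temporal
    # burst, late 22 Hz occipital burst, mirrored across classes), but the
    # two draw independent per-epoch gains: neither alone is reliable, so a
    # classifier is pushed to learn both concepts.  Burst peak amplitudes
    # compensate the short envelope.
    cfg = CohortConfig(
        n_epochs_per_class=24,
        montage=montage,
        signal_spec=(
            (0, SignalSpec(10.0, 2.0, tl, 14.0, early, gain_group="alpha")),
            (0, SignalSpec(22.0, 3.0, ol, 14.0, late, gain_group="beta")),
            (1, SignalSpec(10.0, 2.0, tr, 14.0, early, gain_group="alpha")),
            (1, SignalSpec(22.0, 3.0, orr, 14.0, late, gain_group="beta")),
        ),
        epoch_gain_jitter=0.6,
        noise_spec=(1.0, 10.0),
        artifact_spec=(
            ArtifactSpec("blink",
                         tuple(c for c in ("Fp1", "Fp2", "F7", "F8")
                               if c in montage), 0.25, 60.0),
        ),
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
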
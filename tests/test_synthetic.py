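"""Synthetic cohort generator: planted signals, noise, artifacts, ground truth."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

import eegconcepts as ec
from eegconcepts.synthetic import ConfigurationError

MONTAGE8 = ("Fp1", "Fp2", "C3", "C4", "O1", "O2", "T7", "T8")


def _clean_config(**over):
    base = dict(
        n_subjects=2, n_epochs_per_class=4, montage=MONTAGE8,
        signal_spec=((0, ec.SignalSpec(10.0, 0.0, ("C3",), 5.0)),),
        noise_spec=(1.0, 0.0), artifact_spec=(),
        subject_variability=(0.0, 0.0), seed=11,
    )
    base.update(over)
    return ec.CohortConfig(**base)


def test_noise_free_signal_is_confined_to_planted_channel_and_band():
    epochs = ec.generate_cohort(_clean_config())
    f, p = periodogram(epochs.data, fs=128, axis=-1)
    cls0 = epochs.labels == 0
    c3 = MONTAGE8.index("C3")
    in_band = (f >= 8) & (f < 12)
    assert p[cls0, c3][:, in_band].sum() > 0
    # nothing outside the band on C3, nothing anywhere on other channels
    assert p[cls0, c3][:, ~in_band].sum() < 1e-12 * p[cls0, c3].sum()
    others = np.delete(np.arange(8), c3)
    assert np.abs(epochs.data[:, others]).max() == 0
    # class-1 epochs are silent in this config
    assert np.abs(epochs.data[~cls0]).max() == 0


def test_seeded_generation_is_bit_identical():
    cfg = ec.lateralized_cohort_config(seed=5, n_subjects=2,
                                       n_epochs_per_class=3)
    a = ec.generate_cohort(cfg)
    b = ec.generate_cohort(cfg)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.labels, b.labels)


def test_pink_noise_spectral_slope_near_minus_one():
    cfg = _clean_config(signal_spec=(), noise_spec=(1.0, 10.0),
                        n_epochs_per_class=30)
    epochs = ec.generate_cohort(cfg)
    f, p = periodogram(epochs.data, fs=128, axis=-1)
    sel = (f >= 2) & (f <= 40)
    logf = np.log10(f[sel])
    logp = np.log10(p[..., sel].mean(axis=(0, 1)))
    slope = np.polyfit(logf, logp, 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.2)


def test_all_zero_amplitudes_give_zero_output():
    cfg = _clean_config(
        signal_spec=((0, ec.SignalSpec(10.0, 0.0, ("C3",), 0.0)),),
        artifact_spec=(ec.ArtifactSpec("blink", ("Fp1",), 0.5, 0.0),),
        noise_spec=(1.0, 0.0))
    epochs = ec.generate_cohort(cfg)
    assert np.abs(epochs.data).max() == 0.0


class TestGroundTruth:
    def test_blink_loading_confined_to_frontal_channels(self):
        cfg = _clean_config(
            artifact_spec=(ec.ArtifactSpec("blink", ("Fp1", "Fp2"), 1.0, 50.0),))
        gt = ec.ground_truth(cfg)
        blink = next(s for s in gt.sources if s.kind == "blink")
        nz = np.flatnonzero(blink.loading)
        assert set(nz) == {MONTAGE8.index("Fp1"), MONTAGE8.index("Fp2")}

    def test_source_count_is_signals_plus_artifacts(self):
        cfg = ec.lateralized_cohort_config(seed=1, n_subjects=2,
                                           n_epochs_per_class=2)
        gt = ec.ground_truth(cfg)
        assert len(gt.sources) == len(cfg.signal_spec) + len(cfg.artifact_spec)

    def test_reconstruction_matches_generated_cohort_exactly(self):
        cfg = ec.lateralized_cohort_config(seed=2, n_subjects=2,
                                           n_epochs_per_class=2)
        epochs = ec.generate_cohort(cfg)
        gt = ec.ground_truth(cfg)
        assert np.allclose(gt.reconstruct(), epochs.data)

    def test_blink_time_course_correlates_with_frontal_channel(self):
        cfg = _clean_config(
            signal_spec=(),
            artifact_spec=(ec.ArtifactSpec("blink", ("Fp1",), 1.0, 80.0),),
            noise_spec=(1.0, 2.0), n_epochs_per_class=10)
        epochs = ec.generate_cohort(cfg)
        gt = ec.ground_truth(cfg)
        blink = next(s for s in gt.sources if s.kind == "blink")
        fp1 = epochs.data[:, MONTAGE8.index("Fp1"), :].ravel()
        tc = blink.time_courses.ravel()
        corr = np.corrcoef(fp1, tc)[0, 1]
        assert corr > 0.5


def test_planted_band_power_contrast_has_planted_sign_for_every_subject():
    cfg = ec.lateralized_cohort_config(seed=3, n_subjects=4,
                                       n_epochs_per_class=8)
    epochs = ec.generate_cohort(cfg)
    f, p = periodogram(epochs.data, fs=128, axis=-1)
    band = (f >= 8) & (f < 12)
    chs = list(epochs.channels)
    left = [chs.index(c) for c in ("FC5", "C5", "CP5", "T7")]
    right = [chs.index(c) for c in ("FC6", "C6", "CP6", "T8")]
    alpha = p[..., band].sum(axis=-1)
    contrast = alpha[:, left].mean(axis=1) - alpha[:, right].mean(axis=1)
    for s in range(4):
        m = epochs.subjects == s
        assert contrast[m & (epochs.labels == 0)].mean() > 0
        assert contrast[m & (epochs.labels == 1)].mean() < 0


@pytest.mark.parametrize("bad", [
    dict(signal_spec=((0, ec.SignalSpec(10.0, 0.0, ("Cz",), 5.0)),)),
    dict(artifact_spec=(ec.ArtifactSpec("blink", ("Nope",), 0.5, 1.0),)),
    dict(artifact_spec=(ec.ArtifactSpec("wiggle", ("Fp1",), 0.5, 1.0),)),
    dict(signal_spec=((0, ec.SignalSpec(10.0, 0.0, ("C3",), -1.0)),)),
    dict(epoch_len=3.3),
    dict(montage=("Fp1", "Fp1", "C3", "C4", "O1", "O2", "T7", "T8")),
])
def test_inconsistent_configs_are_rejected(bad):
    with pytest.raises((ConfigurationError, ValueError)):
        ec.generate_cohort(_clean_config(**bad))
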
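"""Neuroscientific views: PSD/relevance curves, band topographies, grouping."""

import numpy as np
import pytest

import eegconcepts as ec
from eegconcepts.relmax import Concept
from eegconcepts.views import RegionMap, channel_positions

CHANNELS = ("Fp1", "Fp2", "FC5", "FC6", "C5", "C6", "O1", "O2")
REGIONS = RegionMap((
    ("left", ("FC5", "C5")),
    ("right", ("FC6", "C6")),
))


def _epochs(data):
    n = data.shape[0]
    return ec.EpochSet(data, np.zeros(n, int), np.zeros(n, int),
                       CHANNELS, 128.0)


def _concept(sample_ids, freq_values, T=384):
    freqs = np.fft.rfftfreq(T, d=1 / 128.0)
    return Concept(model_id="m", layer_id="pointwise_conv", filter_id=0,
                   class_y=0, sample_ids=np.asarray(sample_ids),
                   sample_relevance=np.ones(len(sample_ids)),
                   mean_activation_map=np.ones(96),
                   mean_freq_relevance=ec.FreqRelevance(freq_values, freqs))


class TestPSDRelevanceCurves:
    def test_relevance_percentages_sum_to_100(self, rng):
        data = rng.standard_normal((6, 8, 384))
        fr = np.abs(rng.standard_normal((8, 193)))
        df = ec.psd_relevance_curves([_concept([0, 1], fr)], _epochs(data))
        assert df["relevance_pct"].sum() == pytest.approx(100.0)

    def test_white_noise_cluster_has_flat_psd(self, rng):
        data = rng.standard_normal((80, 8, 384))
        fr = np.ones((8, 193))
        df = ec.psd_relevance_curves([_concept(np.arange(80), fr)],
                                     _epochs(data))
        interior = df["psd"].to_numpy()[1:-1]
        # mean periodogram of 80x8 white-noise rows: variation well below 3x
        assert interior.max() / interior.min() < 3.0

    def test_pure_tone_cluster_peaks_at_the_tone_bin(self):
        t = np.arange(384) / 128.0
        data = np.tile(np.sin(2 * np.pi * 10 * t), (4, 8, 1))
        df = ec.psd_relevance_curves([_concept([0, 1], np.ones((8, 193)))],
                                     _epochs(data))
        assert df["psd"].idxmax() == 30  # 10 Hz at 1/3 Hz resolution

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ec.psd_relevance_curves([], _epochs(np.zeros((1, 8, 384))))


class TestBandTopo:
    def test_uniform_power_scales_to_one_everywhere(self, rng):
        row = rng.standard_normal(384)
        data = np.tile(row, (10, 8, 1))  # identical channels -> equal power
        topo = ec.band_topo([_concept(np.arange(10), np.ones((8, 193)))],
                            _epochs(data))
        assert np.allclose(topo.scaled_power, 1.0)

    def test_all_negative_relevance_gives_zero_maps(self, rng):
        data = rng.standard_normal((4, 8, 384))
        topo = ec.band_topo([_concept([0], -np.ones((8, 193)))],
                            _epochs(data))
        assert np.abs(topo.relevance).max() == 0

    def test_relevance_untouched_by_power_scaling(self, rng):
        data = rng.standard_normal((4, 8, 384))
        fr = np.abs(rng.standard_normal((8, 193)))
        topo = ec.band_topo([_concept([0, 2], fr)], _epochs(data))
        expected, _ = ec.band_aggregate(
            ec.FreqRelevance(fr, np.fft.rfftfreq(384, 1 / 128.0)),
            positive_only=True)
        assert np.array_equal(topo.relevance, expected.T)


class TestFunctionalGrouping:
    def _fr(self, values):
        return ec.FreqRelevance(values, np.fft.rfftfreq(384, 1 / 128.0))

    def test_concentrated_relevance_dominates_its_region(self):
        vals = np.zeros((8, 193))
        vals[CHANNELS.index("FC5")] = 1.0
        vals[CHANNELS.index("C5")] = 1.0
        g = ec.functional_grouping(self._fr(vals), CHANNELS, REGIONS)
        assert (g.loc["left"] > g.loc["right"]).all()

    def test_all_negative_relevance_gives_zero_matrix(self):
        g = ec.functional_grouping(self._fr(-np.ones((8, 193))), CHANNELS,
                                   REGIONS)
        assert np.abs(g.to_numpy()).max() == 0

    def test_absolute_variant_keeps_negative_mass(self):
        g = ec.functional_grouping(self._fr(-np.ones((8, 193))), CHANNELS,
                                   REGIONS, absolute=True)
        assert np.allclose(g.to_numpy(), 1.0)

    def test_concept_order_within_cluster_is_irrelevant(self, rng):
        frs = [np.abs(rng.standard_normal((8, 193))) for _ in range(3)]
        c = [_concept([0], f) for f in frs]
        a = ec.views.cluster_mean_freq_relevance(c)
        b = ec.views.cluster_mean_freq_relevance(c[::-1])
        assert np.allclose(a.values, b.values)


class TestRegionsAndPositions:
    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            RegionMap((("a", ("C5",)), ("b", ("C5", "C6"))))

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            RegionMap((("a", ()),))

    def test_region_channel_missing_from_montage_named_in_error(self):
        with pytest.raises(ValueError, match="FC6"):
            REGIONS.validate_montage(("FC5", "C5", "C6"))

    def test_unknown_channel_position_named_in_error(self):
        with pytest.raises(ValueError, match="NotAChannel"):
            channel_positions(("Cz", "NotAChannel"))

    def test_default_regions_resolve_to_standard_positions(self):
        for name in ec.DEFAULT_REGIONS.names:
            pos = channel_positions(ec.DEFAULT_REGIONS.channels(name))
            assert np.isfinite(pos).all()
            # left regions on the left of the head midline and vice versa
            side = pos[:, 0].mean()
            assert (side < 0) == name.endswith("_left")
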
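"""ICA decomposition, relevance projection, component labelling."""

import numpy as np
import pytest

import eegconcepts as ec


@pytest.fixture(scope="module")
def planted_mixture():
    """3 super-Gaussian sources mixed into 8 channels."""
    rng = np.random.default_rng(5)
    T = 20000
    sources = rng.laplace(size=(3, T))
    mixing = rng.standard_normal((8, 3))
    noise = 0.05 * rng.standard_normal((8, T))
    return mixing @ sources + noise, sources, mixing


class TestFitICA:
    def test_known_mixture_recovered_up_to_permutation_and_sign(
            self, planted_mixture):
        X, sources, _ = planted_mixture
        ica = ec.fit_ica(X, n_components=3, seed=0)
        rec = ica.sources(X)
        corr = np.corrcoef(np.vstack([sources, rec]))[:3, 3:]
        best = np.abs(corr).max(axis=1)
        assert np.all(best > 0.95)

    def test_sources_have_unit_variance(self, planted_mixture):
        X, _, _ = planted_mixture
        ica = ec.fit_ica(X, seed=0)
        assert np.allclose(ica.sources(X).std(axis=1), 1.0, atol=1e-6)

    def test_mixing_inverts_unmixing_on_retained_subspace(self, planted_mixture):
        X, _, _ = planted_mixture
        ica = ec.fit_ica(X, n_components=3, seed=0)
        prod = ica.full_unmixing @ ica.mixing
        assert np.allclose(prod, np.eye(3), atol=1e-8)

    def test_average_referenced_data_drops_one_component(self, rng):
        X = rng.standard_normal((6, 5000))
        X -= X.mean(axis=0, keepdims=True)
        ica = ec.fit_ica(X, seed=0)
        assert ica.n_components == 5

    def test_too_short_recording_rejected(self, rng):
        with pytest.raises(ValueError):
            ec.fit_ica(rng.standard_normal((8, 16)))


class TestProjectRelevance:
    def test_zero_relevance_projects_to_zero(self, planted_mixture):
        X, _, _ = planted_mixture
        ica = ec.fit_ica(X, n_components=3, seed=0)
        assert np.abs(ec.project_relevance(ica, np.zeros_like(X))).max() == 0

    def test_projection_linear_before_absolute_aggregation(self,
                                                           planted_mixture):
        X, _, _ = planted_mixture
        ica = ec.fit_ica(X, n_components=3, seed=0)
        rng = np.random.default_rng(0)
        r1 = rng.standard_normal(X.shape)
        r2 = rng.standard_normal(X.shape)
        lhs = ica.full_unmixing @ (2.0 * r1 + 3.0 * r2)
        rhs = 2.0 * (ica.full_unmixing @ r1) + 3.0 * (ica.full_unmixing @ r2)
        assert np.allclose(lhs, rhs)

    def test_ranking_invariant_to_component_sign_flips(self, planted_mixture):
        X, _, _ = planted_mixture
        ica = ec.fit_ica(X, n_components=3, seed=0)
        rng = np.random.default_rng(1)
        R = rng.standard_normal(X.shape)
        base = ec.project_relevance(ica, R)
        flipped = ec.ICADecomposition(
            pre_scale=ica.pre_scale, whitening=ica.whitening,
            unmixing=-ica.unmixing, source_scale=ica.source_scale,
            mixing=-ica.mixing, n_samples=ica.n_samples)
        assert np.allclose(ec.project_relevance(flipped, R), base)

    def test_shape_mismatch_rejected(self, planted_mixture):
        X, _, _ = planted_mixture
        ica = ec.fit_ica(X, n_components=3, seed=0)
        with pytest.raises(ValueError):
            ec.project_relevance(ica, np.zeros((4, 100)))


class TestLabeling:
    @pytest.fixture(scope="class")
    def blink_cohort(self):
        cfg = ec.CohortConfig(
            n_subjects=2, n_epochs_per_class=10,
            montage=("Fp1", "Fp2", "F3", "F4", "C3", "C4", "O1", "O2"),
            signal_spec=((0, ec.SignalSpec(10.0, 1.0, ("C3",), 4.0)),
                         (1, ec.SignalSpec(10.0, 1.0, ("C4",), 4.0))),
            noise_spec=(1.0, 3.0),
            artifact_spec=(
                ec.ArtifactSpec("blink", ("Fp1", "Fp2"), 1.0, 80.0),),
            subject_variability=(0.0, 0.0), seed=21)
        return cfg, ec.generate_cohort(cfg)

    def test_ground_truth_labeler_marks_blink_component_as_eye(
            self, blink_cohort):
        cfg, epochs = blink_cohort
        ica = ec.fit_ica(epochs.data, seed=0)
        truth = ec.ground_truth(cfg)
        labels = ec.label_components(ica, ec.GroundTruthLabeler(truth))
        assert len(labels) == ica.n_components
        assert any(lab == "eye" for lab, _ in labels)

    def test_blink_component_ranks_high_for_blink_focused_relevance(
            self, blink_cohort):
        cfg, epochs = blink_cohort
        ica = ec.fit_ica(epochs.data, seed=0)
        truth = ec.ground_truth(cfg)
        labels = ec.label_components(ica, ec.GroundTruthLabeler(truth))
        blink = next(s for s in truth.sources if s.kind == "blink")
        R = blink.loading[None, :, None] * blink.time_courses[:, None, :]
        rel = ec.project_relevance(ica, R)
        top2 = np.argsort(rel)[::-1][:2]
        assert any(labels[i][0] == "eye" for i in top2)

    def test_missing_labeler_degrades_to_unlabelled(self, planted_mixture):
        X, _, _ = planted_mixture
        ica = ec.fit_ica(X, n_components=3, seed=0)
        labels = ec.label_components(ica, None)
        assert labels == [("unlabelled", 0.0)] * 3

    def test_external_adapter_degrades_gracefully_when_unavailable(
            self, planted_mixture):
        X, _, _ = planted_mixture
        ica = ec.fit_ica(X, n_components=3, seed=0)
        labels = ec.label_components(ica, ec.ICLabelAdapter())
        assert len(labels) == 3
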
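"""EEGNet construction, activations, training determinism and LOO folds."""

import numpy as np
import pytest

import eegconcepts as ec
from eegconcepts.nn.train import _fold_seed


def expected_param_count(C, T, F1=8, D=2, F2=16, kt=64, ks=16,
                         pool1=4, pool2=8, n_classes=2):
    """Independent hand-sum of the per-layer parameter formulas."""
    temporal = F1 * kt
    bn1 = 2 * F1
    spatial = F1 * D * C
    bn2 = 2 * F1 * D
    sep_depthwise = F1 * D * ks
    pointwise = F2 * F1 * D
    bn3 = 2 * F2
    dense = n_classes * F2 * (T // (pool1 * pool2)) + n_classes
    return (temporal + bn1 + spatial + bn2 + sep_depthwise + pointwise
            + bn3 + dense)


class TestBuild:
    def test_parameter_count_matches_layer_shape_formulas(self):
        model = ec.build_eegnet(32, 384, seed=0)
        assert model.n_params == expected_param_count(32, 384) == 2002

    def test_zero_weight_model_predicts_uniform(self):
        model = ec.build_eegnet(8, 128, seed=0)
        for layer in model.trainable_layers():
            for p in layer.params().values():
                p[...] = 0
        x = np.random.default_rng(0).standard_normal((4, 8, 128))
        logits = model.forward(x)
        assert np.abs(logits).max() == 0
        assert np.allclose(model.predict_proba(x), 0.5)

    def test_same_seed_gives_identical_initial_weights(self):
        a = ec.build_eegnet(8, 128, seed=9)
        b = ec.build_eegnet(8, 128, seed=9)
        for la, lb in zip(a.layers, b.layers):
            for k in la.params():
                assert np.array_equal(la.params()[k], lb.params()[k])

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            ec.build_eegnet(8, 32, seed=0)

    def test_softmax_rows_sum_to_one(self, rng):
        model = ec.build_eegnet(8, 128, seed=1)
        p = model.predict_proba(rng.standard_normal((5, 8, 128)))
        assert np.allclose(p.sum(axis=1), 1.0)


class TestActivations:
    def test_last_conv_yields_16_filter_maps(self, rng):
        model = ec.build_eegnet(8, 128, seed=0)
        acts = ec.forward_activations(
            model, rng.standard_normal((3, 8, 128)), ec.LAST_CONV_LAYER)
        assert acts.shape == (3, 16, 128 // 4)

    def test_zero_input_bias_free_model_gives_zero_activations(self):
        model = ec.build_eegnet(8, 128, seed=0, dense_bias=False)
        canon = ec.canonicalize(model)  # removes batch-norm shifts
        acts = ec.forward_activations(canon, np.zeros((2, 8, 128)),
                                      ec.LAST_CONV_LAYER)
        assert np.abs(acts).max() == 0

    def test_recomputation_is_identical(self, rng):
        model = ec.build_eegnet(8, 128, seed=0)
        x = rng.standard_normal((3, 8, 128))
        a = ec.forward_activations(model, x, ec.LAST_CONV_LAYER)
        b = ec.forward_activations(model, x, ec.LAST_CONV_LAYER)
        assert np.array_equal(a, b)

    def test_truncation_matches_full_forward(self, rng):
        model = ec.build_eegnet(8, 128, seed=2)
        x = rng.standard_normal((2, 8, 128))
        acts = ec.forward_activations(model, x, "temporal_conv")
        h = model._to_input(x)
        h = model.layers[0].forward(h)
        assert np.allclose(acts, h.reshape(2, 8, -1))

    def test_non_convolutional_layer_rejected(self, rng):
        model = ec.build_eegnet(8, 128, seed=0)
        with pytest.raises(ValueError):
            ec.forward_activations(model, rng.standard_normal((1, 8, 128)),
                                   "dense")


class TestTrainingDeterminism:
    def test_same_seed_training_is_bit_reproducible(self, rng):
        x = rng.standard_normal((16, 8, 128))
        y = np.array([0, 1] * 8)
        weights = []
        for _ in range(2):
            model = ec.build_eegnet(8, 128, seed=4)
            ec.train_model(model, x, y, epochs=3, batch_size=8,
                           rng=np.random.default_rng(4))
            weights.append(model["dense"].w.copy())
        assert np.array_equal(weights[0], weights[1])

    def test_same_seed_mode_fold_models_share_initial_weights(self, tiny_cohort):
        runs = ec.train_loo(tiny_cohort, seed_mode="same", n_reps=1, epochs=0)
        assert len({r.seed for r in runs}) == 1
        w0 = runs[0].model["temporal_conv"].w
        for r in runs[1:]:
            assert np.array_equal(w0, r.model["temporal_conv"].w)

    def test_unique_seed_mode_fold_seeds_differ(self):
        seeds = {_fold_seed(0, 0, f) for f in range(6)}
        assert len(seeds) == 6
        assert all(s < 2 ** 31 for s in seeds)


class TestLOO:
    def test_one_run_per_rep_and_subject(self, tiny_cohort):
        runs = ec.train_loo(tiny_cohort, n_reps=2, epochs=1)
        assert len(runs) == 2 * 3
        assert {(r.rep, r.subject) for r in runs} == {
            (rep, s) for rep in range(2) for s in range(3)}

    def test_single_class_training_fold_rejected(self, tiny_cohort):
        broken = tiny_cohort.copy()
        broken.labels[broken.subjects != 0] = 1
        with pytest.raises(ValueError):
            ec.train_loo(broken, n_reps=1, epochs=1)

    def test_fewer_than_two_subjects_rejected(self, tiny_cohort):
        solo = tiny_cohort.select(tiny_cohort.subjects == 0)
        with pytest.raises(ValueError):
            ec.train_loo(solo, n_reps=1, epochs=1)

    def test_label_shuffled_cohort_scores_at_chance(self):
        cfg = ec.lateralized_cohort_config(
            seed=13, n_subjects=3, n_epochs_per_class=8)
        cohort = ec.generate_cohort(cfg)
        pre = ec.preprocess_epochs(cohort)
        shuffler = np.random.default_rng(13)
        pre.labels = shuffler.permutation(pre.labels)
        runs = ec.train_loo(pre, n_reps=1, epochs=30, base_seed=13)
        mean_acc = np.mean([r.accuracy for r in runs])
        assert mean_acc == pytest.approx(0.5, abs=0.1)
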
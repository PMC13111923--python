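"""Relevance propagation: rules, canonicalization, conservation, conditioning."""

import numpy as np
import pytest

import eegconcepts as ec
from eegconcepts.crp import Composite, Condition, propagate_layer, lrp, crp
from eegconcepts.nn.layers import AvgPool, Dense, Flatten, ReLU
from eegconcepts.nn.model import LayerGraph


def make_toy_mlp(w1, w2, n_in):
    """Bias-free linear -> ReLU -> linear stack on flat inputs [B, n_in, 1]."""
    rng = np.random.default_rng(0)
    d1 = Dense(w1.shape[1], w1.shape[0], rng, bias=False, max_norm=None,
               name="d1")
    d1.w = w1.astype(np.float32)
    d2 = Dense(w2.shape[1], w2.shape[0], rng, bias=False, max_norm=None,
               name="d2")
    d2.w = w2.astype(np.float32)
    return LayerGraph([Flatten(), d1, ReLU(), d2], n_channels=n_in, n_times=1)


class TestCanonicalize:
    def test_identity_batchnorm_leaves_weights_unscaled(self):
        model = ec.build_eegnet(8, 128, seed=0)
        for name in ("bn1", "bn2", "bn3"):
            model[name].eps = 0.0  # gamma=1, beta=0, mean=0, var=1 -> identity
        canon = ec.canonicalize(model)
        assert np.allclose(canon["temporal_conv"].w, model["temporal_conv"].w)
        assert canon["temporal_conv"].b is None

    def test_forward_agreement_on_random_model(self, rng):
        model = ec.build_eegnet(8, 128, seed=1)
        # give batch-norm non-trivial statistics
        x = rng.standard_normal((32, 8, 128)).astype(np.float32)
        model.forward(x, training=True, rng=rng)
        canon = ec.canonicalize(model)
        a = model.forward(x)
        b = canon.forward(x)
        assert np.abs(a - b).max() < 1e-5 * max(1.0, np.abs(a).max())

    def test_idempotent(self, rng):
        model = ec.build_eegnet(8, 128, seed=2)
        once = ec.canonicalize(model)
        twice = ec.canonicalize(once)
        x = rng.standard_normal((4, 8, 128))
        assert np.array_equal(once.forward(x), twice.forward(x))

    def test_batchnorm_layers_removed(self):
        canon = ec.canonicalize(ec.build_eegnet(8, 128, seed=0))
        assert all(l.kind != "batchnorm" for l in canon.layers)


class TestPropagateLayer:
    def test_lrp0_redistributes_linear_map_by_contribution(self):
        rng = np.random.default_rng(0)
        d = Dense(2, 1, rng, bias=False, max_norm=None)
        d.w = np.array([[2.0, 3.0]], dtype=np.float32)
        a = np.array([[1.0, 1.0]])
        R = np.array([[5.0]])
        out = propagate_layer(("lrp0",), d, a, R)
        assert np.allclose(out, [[2.0, 3.0]], atol=1e-9)

    def test_alphabeta_equals_lrp0_when_all_contributions_positive(self):
        rng = np.random.default_rng(1)
        d = Dense(4, 3, rng, bias=False, max_norm=None)
        d.w = rng.uniform(0.1, 1.0, size=(3, 4)).astype(np.float32)
        a = rng.uniform(0.1, 1.0, size=(2, 4))
        R = rng.uniform(0.1, 1.0, size=(2, 3))
        ab = propagate_layer(("alphabeta", 2.0, 1.0), d, a, R)
        l0 = propagate_layer(("lrp0",), d, a, R)
        assert np.allclose(ab, l0, rtol=1e-9)

    def test_uniform_pool_splits_relevance_equally(self):
        pool = AvgPool(4)
        a = np.ones((1, 1, 1, 4))
        R = np.array([[[[1.0]]]])
        out = propagate_layer(("epsilon", 1e-6), pool, a, R)
        assert np.allclose(out, 0.25, rtol=1e-5)

    def test_epsilon_rule_conserves_in_the_small_eps_limit(self, rng):
        d = Dense(6, 3, rng, bias=False, max_norm=None)
        a = rng.standard_normal((4, 6))
        R = rng.standard_normal((4, 3))
        outs = [propagate_layer(("epsilon", eps), d, a, R).sum()
                for eps in (1e-2, 1e-4, 1e-8)]
        errs = [abs(o - R.sum()) for o in outs]
        assert errs[2] < errs[0]
        assert errs[2] < 1e-6 * max(1.0, abs(R.sum()))


class TestLRP:
    def test_lrp0_equals_gradient_times_input_on_relu_toy_net(self, rng):
        w1 = rng.standard_normal((5, 6))
        w2 = rng.standard_normal((2, 5))
        toy = make_toy_mlp(w1, w2, n_in=6)
        x = rng.standard_normal((7, 6, 1))
        rt = lrp(toy, x, class_y=0, composite=Composite.all_lrp0())
        # independent oracle: explicit chain-rule gradient of the toy net
        w1f = toy["d1"].w.astype(np.float64)
        w2f = toy["d2"].w.astype(np.float64)
        z = x[:, :, 0] @ w1f.T
        grad = (w2f[0] * (z > 0)) @ w1f
        expected = grad * x[:, :, 0]
        assert np.abs(rt.values[:, :, 0] - expected).max() < 1e-6

    def test_zero_logit_gives_zero_relevance(self):
        model = ec.build_eegnet(8, 128, seed=0)
        for layer in model.trainable_layers():
            for p in layer.params().values():
                p[...] = 0
        canon = ec.canonicalize(model)
        rt = lrp(canon, np.random.default_rng(0).standard_normal((2, 8, 128)),
                 class_y=0)
        assert np.abs(rt.values).max() == 0

    def test_conservation_on_bias_free_eegnet(self, random_canonical_model,
                                              rng):
        x = rng.standard_normal((6, 32, 384))
        logits = random_canonical_model.forward(x)
        rt = lrp(random_canonical_model, x, class_y=1)
        ratio = rt.per_sample_total() / logits[:, 1]
        assert np.all(ratio > 0.9)
        assert np.all(ratio < 1.0 + 1e-5)


class TestCRP:
    def test_singleton_conditions_partition_the_lrp_heatmap(
            self, random_canonical_model, rng):
        x = rng.standard_normal((3, 32, 384))
        full = lrp(random_canonical_model, x, class_y=0).values
        acc = np.zeros_like(full)
        for f in range(16):
            acc += crp(random_canonical_model, x,
                       Condition(filters=(f,), class_y=0)).values
        scale = np.abs(full).max()
        assert np.abs(acc - full).max() < 1e-6 * scale

    def test_full_filter_set_equals_unconditioned_lrp(
            self, random_canonical_model, rng):
        x = rng.standard_normal((2, 32, 384))
        full = lrp(random_canonical_model, x, class_y=1).values
        allf = crp(random_canonical_model, x,
                   Condition(filters=tuple(range(16)), class_y=1)).values
        assert np.allclose(allf, full)

    def test_disjoint_sets_are_additive(self, random_canonical_model, rng):
        x = rng.standard_normal((2, 32, 384))
        r1 = crp(random_canonical_model, x,
                 Condition(filters=(0, 1, 5), class_y=0)).values
        r2 = crp(random_canonical_model, x,
                 Condition(filters=(2, 9), class_y=0)).values
        ru = crp(random_canonical_model, x,
                 Condition(filters=(0, 1, 2, 5, 9), class_y=0)).values
        assert np.abs(r1 + r2 - ru).max() < 1e-9

    def test_empty_filter_set_rejected(self, random_canonical_model):
        with pytest.raises(ValueError):
            crp(random_canonical_model, np.zeros((1, 32, 384)),
                Condition(filters=(), class_y=0))

    def test_out_of_range_filter_rejected(self, random_canonical_model):
        with pytest.raises(ValueError):
            Condition(filters=(99,), class_y=0).validate(
                random_canonical_model)


class TestComposite:
    def test_alpha_beta_must_differ_by_one(self):
        with pytest.raises(ValueError):
            Composite({"dense": ("alphabeta", 2.0, 0.5)})

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            Composite({"dense": ("epsilon", 0.0)})
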
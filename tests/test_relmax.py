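"""Relevance maximization: sample scoring, top-k selection, concept building."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegconcepts as ec
from eegconcepts.crp import Condition
from eegconcepts.relmax import select_top_k


class TestSelectTopK:
    def test_dominant_first_score_forces_k_of_one(self):
        sel = select_top_k(np.array([50.0, 30.0, 10.0, 5.0, 5.0]),
                           mass_fraction=0.2)
        assert list(sel) == [0]

    def test_ten_equal_scores_force_k_of_two(self):
        sel = select_top_k(np.ones(10), mass_fraction=0.2)
        assert len(sel) == 2

    def test_selection_is_descending_and_positive(self):
        scores = np.array([0.5, -3.0, 2.0, 0.1, 4.0])
        sel = select_top_k(scores, mass_fraction=0.9)
        assert all(scores[i] > 0 for i in sel)
        assert list(scores[sel]) == sorted(scores[sel], reverse=True)

    def test_all_nonpositive_scores_give_empty_selection(self):
        assert len(select_top_k(np.array([-1.0, 0.0, -0.5]))) == 0

    def test_ties_break_by_sample_index(self):
        sel = select_top_k(np.array([1.0, 1.0, 1.0, 1.0]), mass_fraction=0.5)
        assert list(sel) == [0, 1]

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1,
                    max_size=30),
           st.floats(0.05, 0.45), st.floats(0.5, 0.95))
    def test_raising_mass_fraction_never_decreases_k(self, scores, lo, hi):
        scores = np.asarray(scores)
        if not (scores > 0).any():
            return
        assert len(select_top_k(scores, lo)) <= len(select_top_k(scores, hi))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1,
                    max_size=60))
    def test_cap_is_never_exceeded(self, scores):
        assert len(select_top_k(np.asarray(scores), 0.99, cap=10)) <= 10


class TestScoreSamples:
    def test_scores_match_independent_crp_recomputation(
            self, random_canonical_model, tiny_cohort):
        # the tiny cohort has 8 channels; use a matching model
        model = ec.canonicalize(ec.build_eegnet(8, 384, seed=1,
                                                dense_bias=False))
        cond = Condition(filters=(3,), class_y=0)
        ids, scores = ec.score_samples(model, tiny_cohort, cond)
        assert np.all(tiny_cohort.labels[ids] == 0)
        rt = ec.crp(model, tiny_cohort.data[ids], cond)
        assert np.allclose(scores, rt.values.sum(axis=(1, 2)))

    def test_duplicated_sample_gets_duplicated_score(self, tiny_cohort):
        model = ec.canonicalize(ec.build_eegnet(8, 384, seed=1,
                                                dense_bias=False))
        dup = tiny_cohort.copy()
        dup.data[1] = dup.data[0]
        dup.labels[1] = dup.labels[0]
        cond = Condition(filters=(0,), class_y=int(dup.labels[0]))
        ids, scores = ec.score_samples(model, dup, cond)
        lut = dict(zip(ids.tolist(), scores))
        assert lut[0] == pytest.approx(lut[1], rel=1e-9)

    def test_missing_class_rejected(self, tiny_cohort):
        model = ec.canonicalize(ec.build_eegnet(8, 384, seed=1))
        only0 = tiny_cohort.select(tiny_cohort.labels == 0)
        with pytest.raises(ValueError):
            ec.score_samples(model, only0, Condition(filters=(0,), class_y=1))


class TestBuildConcept:
    @pytest.fixture(scope="class")
    def model(self):
        return ec.canonicalize(ec.build_eegnet(8, 384, seed=2,
                                               dense_bias=False))

    def test_k_of_one_map_equals_that_samples_map(self, model, tiny_cohort):
        cond = Condition(filters=(2,), class_y=0)
        concept = ec.build_concept(model, tiny_cohort, cond, cap=1,
                                   with_frequency=False)
        assert concept.k == 1
        acts = ec.forward_activations(
            model, tiny_cohort.data[concept.sample_ids], cond.layer_id)
        assert np.allclose(concept.mean_activation_map, acts[0, 2])

    def test_mean_map_invariant_to_selection_order(self, model, tiny_cohort):
        cond = Condition(filters=(5,), class_y=1)
        concept = ec.build_concept(model, tiny_cohort, cond,
                                   with_frequency=False)
        if concept.k < 2:
            pytest.skip("needs at least two selected samples")
        acts = ec.forward_activations(
            model, tiny_cohort.data[concept.sample_ids[::-1]], cond.layer_id)
        assert np.allclose(concept.mean_activation_map,
                           acts[:, 5].mean(axis=0), atol=1e-6)

    def test_map_length_follows_the_pooling_chain(self, model, tiny_cohort):
        cond = Condition(filters=(0,), class_y=0)
        concept = ec.build_concept(model, tiny_cohort, cond,
                                   with_frequency=False)
        # the pointwise conv sits after the first pooling stage only
        assert len(concept.mean_activation_map) == 384 // 4

    def test_concept_count_per_model(self, model, tiny_cohort):
        concepts = ec.concepts_for_model(model, tiny_cohort,
                                         with_frequency=False)
        assert len(concepts) <= 16 * 2
        assert all(1 <= c.k <= 10 for c in concepts)
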
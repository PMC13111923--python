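"""Shared fixtures.

The two expensive fixtures (leave-one-out trainings on the planted cohorts)
are session-scoped and shared between the synthetic-recovery, clustering
and view tests so each cohort is trained exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import eegconcepts as ec


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 4 epochs/class, 8 channels: cheap epoched data."""
    cfg = ec.lateralized_cohort_config(
        seed=7, n_subjects=3, n_epochs_per_class=4,
        montage=("Fp1", "Fp2", "FC5", "FC6", "C5", "C6", "O1", "O2"),
        signal_spec=(
            (0, ec.SignalSpec(10.0, 2.0, ("FC5", "C5"), 8.0)),
            (1, ec.SignalSpec(10.0, 2.0, ("FC6", "C6"), 8.0)),
        ),
        artifact_spec=(ec.ArtifactSpec("blink", ("Fp1", "Fp2"), 0.3, 60.0),),
    )
    return ec.generate_cohort(cfg)


@pytest.fixture(scope="session")
def random_canonical_model():
    """Bias-free, canonicalized, randomly initialized EEGNet (32 ch, 3 s)."""
    model = ec.build_eegnet(32, 384, seed=3, dense_bias=False)
    return ec.canonicalize(model)


@pytest.fixture(scope="session")
def lateralized_experiment():
    """The scaled-down study: 6-subject 10 Hz-lateralized cohort, one
    leave-one-out repetition of 200 training epochs, plus the per-filter
    concepts (with frequency relevance) of every fold model."""
    cfg = ec.lateralized_cohort_config(seed=0)
    cohort = ec.generate_cohort(cfg)
    pre = ec.preprocess_epochs(cohort)
    runs = ec.train_loo(pre, seed_mode="unique", n_reps=1, epochs=200,
                        batch_size=128, base_seed=0)
    concepts = []
    for run in runs:
        test = pre.select(pre.subjects == run.subject)
        canon = ec.canonicalize(run.model)
        concepts.extend(ec.concepts_for_model(
            canon, test, model_id=f"subj{run.subject:02d}"))
    return {"config": cfg, "cohort": cohort, "pre": pre, "runs": runs,
            "concepts": concepts}


@pytest.fixture(scope="session")
def two_concept_experiment():
    """Two planted concept types per class (alpha-temporal early burst,
    beta-occipital late burst), trained leave-one-out, with per-filter
    concepts for every fold model."""
    cfg = ec.two_concept_cohort_config(seed=0)
    cohort = ec.generate_cohort(cfg)
    pre = ec.preprocess_epochs(cohort)
    runs = ec.train_loo(pre, seed_mode="unique", n_reps=1, epochs=150,
                        batch_size=128, base_seed=1)
    concepts = []
    for run in runs:
        test = pre.select(pre.subjects == run.subject)
        canon = ec.canonicalize(run.model)
        concepts.extend(ec.concepts_for_model(
            canon, test, model_id=f"subj{run.subject:02d}",
            with_frequency=False))
    return {"config": cfg, "pre": pre, "runs": runs, "concepts": concepts}
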
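"""Training: Adam on cross-entropy, leave-one-subject-out cross-validation.

Training is deterministic: all randomness (initialization, shuffling,
dropout) flows from one ``numpy`` Generator per model, so two runs with the
same seed and data are bit-identical.  Under leave-one-out cross-validation
each fold holds out one subject entirely; the two seed regimes either give
every fold model its own seed (``unique``) or share one seed per repetition
(``same``), which isolates stochastic-optimization variance from
training-set variance when comparing learned concepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..synthetic import EpochSet
from .model import LayerGraph, build_eegnet

__all__ = ["TrainRun", "Adam", "train_model", "evaluate", "train_loo"]


@dataclass
class TrainRun:
    rep: int
    subject: int
    seed_mode: str
    seed: int
    model: LayerGraph
    accuracy: float
    loss_history: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


class Adam:
    """Adam with the customary defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, model: LayerGraph, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for layer in model.trainable_layers():
            for key, p in layer.params().items():
                self.m[(layer.name, key)] = np.zeros_like(p, dtype=np.float32)
                self.v[(layer.name, key)] = np.zeros_like(p, dtype=np.float32)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for layer in self.model.trainable_layers():
            grads = layer.grads()
            for key, p in layer.params().items():
                g = grads[key].astype(np.float32, copy=False)
                m = self.m[(layer.name, key)]
                v = self.v[(layer.name, key)]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            layer.apply_constraints()


def _softmax_xent(logits, y):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-30)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


def train_model(model: LayerGraph, X, y, *, epochs: int, batch_size: int = 128,
                lr: float = 1e-3, rng: np.random.Generator,
                shuffle: bool = True) -> list[float]:
    """Train in place; returns the per-epoch mean loss history."""
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    opt = Adam(model, lr=lr)
    history = []
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = model.forward(X[idx], training=True, rng=rng)
            loss, g = _softmax_xent(logits, y[idx])
            model.backward(g)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def evaluate(model: LayerGraph, X, y) -> float:
    pred = model.predict(np.asarray(X, dtype=np.float32))
    return float((pred == np.asarray(y)).mean())


def _fold_seed(base_seed: int, rep: int, fold: int | None) -> int:
    key = (base_seed, rep) if fold is None else (base_seed, rep, fold)
    # stable < 2**31 seed derived from the tuple
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2 ** 31))


def train_loo(cohort: EpochSet, *, seed_mode: str = "unique", n_reps: int = 1,
              epochs: int = 500, batch_size: int = 128, lr: float = 1e-3,
              base_seed: int = 0, model_kwargs: dict | None = None
              ) -> list[TrainRun]:
    """Leave-one-subject-out cross-validation under a seed regime.

    ``seed_mode='same'`` gives every fold model of a repetition the same
    seed; ``'unique'`` gives each its own.  Returns one :class:`TrainRun`
    per (repetition, held-out subject), with accuracy computed on the
    held-out subject only.
    """
    if seed_mode not in ("unique", "same"):
        raise ValueError("seed_mode must be 'unique' or 'same'")
    subjects = np.unique(cohort.subjects)
    if len(subjects) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    model_kwargs = model_kwargs or {}
    runs = []
    for rep in range(n_reps):
        for fold, held_out in enumerate(subjects):
            test_mask = cohort.subjects == held_out
            train_set = cohort.select(~test_mask)
            test_set = cohort.select(test_mask)
            if len(np.unique(train_set.labels)) < 2:
                raise ValueError("training fold contains a single class")
            seed = _fold_seed(base_seed, rep, None if seed_mode == "same"
                              else fold)
            rng = np.random.default_rng(seed)
            model = build_eegnet(cohort.n_channels, cohort.n_times,
                                 rng=rng, **model_kwargs)
            history = train_model(model, train_set.data, train_set.labels,
                                  epochs=epochs, batch_size=batch_size,
                                  lr=lr, rng=rng)
            acc = evaluate(model, test_set.data, test_set.labels)
            runs.append(TrainRun(rep=rep, subject=int(held_out),
                                 seed_mode=seed_mode, seed=seed, model=model,
                                 accuracy=acc, loss_history=history))
    return runs
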
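"""Cross-model concept consistency under stochastic training variance.

Two trained models are compared through their filters' mean activation
maps: filters of model A are matched to filters of model B by cosine
similarity (optimal bipartite assignment, removing the arbitrary filter
order), B's maps are reordered accordingly, both stacks are flattened and
their Pearson correlation taken.  Averaging over all unordered model pairs
of a leave-one-out repetition, and then over repetitions, yields the
consistency statistic that is compared between the unique-seed and
same-seed training conditions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import t as t_dist

__all__ = ["ConsistencyReport", "match_filters", "pair_correlation",
           "mean_pairwise_correlation", "consistency_report"]

logger = logging.getLogger(__name__)


def match_filters(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Optimal filter assignment maximizing total cosine similarity.

    ``maps_*`` are [n_filters, map_len] stacks of mean activation maps.
    Returns ``perm`` such that ``maps_b[perm[i]]`` is the partner of
    ``maps_a[i]``.
    """
    a = np.asarray(maps_a, dtype=np.float64)
    b = np.asarray(maps_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("filter map stacks must have equal shapes")
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    sim = (a / np.maximum(na, 1e-30)) @ (b / np.maximum(nb, 1e-30)).T
    _, cols = linear_sum_assignment(-sim)
    return cols


def pair_correlation(maps_a: np.ndarray, maps_b: np.ndarray,
                     perm: np.ndarray) -> float:
    """Pearson correlation of the flattened, permutation-aligned map stacks.

    Returns ``nan`` (with a log message) when either flattened vector has
    zero variance.
    """
    va = np.asarray(maps_a, dtype=np.float64).ravel()
    vb = np.asarray(maps_b, dtype=np.float64)[perm].ravel()
    if va.std() == 0 or vb.std() == 0:
        logger.warning("zero-variance activation maps; correlation undefined")
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def mean_pairwise_correlation(model_maps: list[np.ndarray]) -> float:
    """Mean matched correlation over all unordered model pairs."""
    if len(model_maps) < 2:
        raise ValueError("need at least 2 models")
    vals = []
    for a, b in itertools.combinations(model_maps, 2):
        perm = match_filters(a, b)
        vals.append(pair_correlation(a, b, perm))
    return float(np.nanmean(vals))


@dataclass
class ConsistencyReport:
    """Per-condition, per-class consistency across LOO repetitions."""

    table: pd.DataFrame  # condition, class, rep, mean_correlation
    summary: pd.DataFrame  # condition, class, mean, ci_lo, ci_hi
    ci_level: float


def consistency_report(runs_by_condition: dict, ci_level: float = 0.95
                       ) -> ConsistencyReport:
    """Summarize consistency per condition and class.

    ``runs_by_condition`` maps a condition name to a list (over repetitions)
    of dicts ``{class_y: [maps of model 1, maps of model 2, ...]}`` where
    each entry is an [n_filters, map_len] array.  Repetitions with fewer
    than two models are skipped (logged).  Confidence intervals are
    t-based over repetitions; the level is configurable (0.95 default,
    0.90 also in common use).
    """
    rows = []
    for cond, reps in runs_by_condition.items():
        for rep, by_class in enumerate(reps):
            for class_y, model_maps in by_class.items():
                if len(model_maps) < 2:
                    logger.warning("condition %s rep %d class %s: fewer than "
                                   "2 models, skipped", cond, rep, class_y)
                    continue
                rows.append({
                    "condition": cond, "class": class_y, "rep": rep,
                    "mean_correlation":
                        mean_pairwise_correlation(model_maps),
                })
    table = pd.DataFrame(rows)
    summaries = []
    for (cond, class_y), grp in table.groupby(["condition", "class"]):
        vals = grp["mean_correlation"].to_numpy()
        mean = float(np.mean(vals))
        if len(vals) > 1:
            sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            half = float(t_dist.ppf(0.5 + ci_level / 2, len(vals) - 1) * sem)
        else:
            half = 0.0
        summaries.append({"condition": cond, "class": class_y, "mean": mean,
                          "ci_lo": mean - half, "ci_hi": mean + half,
                          "n_reps": len(vals)})
    return ConsistencyReport(table=table, summary=pd.DataFrame(summaries),
                             ci_level=ci_level)
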
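"""Disjoint-undersampling bagging of cost-sensitive SVM weak learners.

The majority class N is partitioned into T = floor(|N| / |P|) disjoint,
minority-sized random subsets N_1..N_T; each balanced set D_i = N_i U P
trains one weighted-SVM weak learner H_i, and the ensemble predicts by
majority vote over the T learners. Unlike bootstrap bagging, every
non-leftover majority sample is seen by exactly one learner and every
minority sample by all of them, so no majority information is discarded
beyond the |N| mod |P| leftover.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ClinicalTable
from .wsvm import WeakClassifier, WeightedSVMConfig, train

logger = logging.getLogger("underbag")


def compute_T(n_neg: int, n_pos: int) -> int:
    """Number of weak learners: floor(|N| / |P|), at least 1.

    With |N| = 52,411 and |P| = 802 this gives T = 65. If the majority is
    smaller than the minority T is forced to 1 with a warning.
    """
    if n_pos <= 0:
        raise ValueError("n_pos must be >= 1")
    if n_neg < n_pos:
        warnings.warn(
            "majority class smaller than minority; forcing T = 1", stacklevel=2
        )
        return 1
    return int(n_neg // n_pos)


@dataclass(frozen=True)
class PartitionPlan:
    """T disjoint minority-sized blocks over the majority indices plus the
    leftover (|N| mod |P|) indices that no learner sees."""

    subsets: tuple[np.ndarray, ...]
    leftover: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        sizes = {len(s) for s in self.subsets}
        if len(sizes) > 1:
            raise ValueError("all subsets must have equal size |P|")
        all_idx = np.concatenate(list(self.subsets) + [self.leftover])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("subsets and leftover must be pairwise disjoint")

    @property
    def T(self) -> int:
        return len(self.subsets)


def partition_majority(
    majority_indices: np.ndarray, n_pos: int, T: int, seed: int
) -> PartitionPlan:
    """Shuffle the majority indices with the seeded generator and cut T
    consecutive blocks of size ``n_pos``; the remainder is the leftover.

    Identical seed gives an identical plan. Raises if T * n_pos exceeds
    the majority size.
    """
    majority_indices = np.asarray(majority_indices)
    if T * n_pos > len(majority_indices):
        raise ValueError(
            f"cannot cut {T} blocks of {n_pos} from {len(majority_indices)} "
            "majority samples"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(majority_indices)
    subsets = tuple(
        shuffled[i * n_pos : (i + 1) * n_pos] for i in range(T)
    )
    leftover = shuffled[T * n_pos :]
    if len(leftover):
        logger.info(
            "partition_majority: %d leftover majority samples discarded",
            len(leftover),
        )
    return PartitionPlan(subsets=subsets, leftover=leftover, seed=seed)


class EnsembleModel:
    """T weak classifiers plus the aggregation rule H(x).

    ``aggregation="vote"`` (default) predicts 1 when at least
    ceil((T+1)/2) learners vote 1; an exact tie at even T goes to the
    positive class (logged once), favoring sensitivity.
    ``aggregation="mean"`` averages decision values instead and
    thresholds at 0.
    """

    def __init__(
        self,
        weak_classifiers: list[WeakClassifier],
        plan: PartitionPlan,
        config: WeightedSVMConfig,
        aggregation: str = "vote",
    ):
        if not weak_classifiers:
            raise ValueError("ensemble needs at least one weak classifier")
        if aggregation not in ("vote", "mean"):
            raise ValueError("aggregation must be 'vote' or 'mean'")
        n_feat = {h.n_features for h in weak_classifiers}
        if len(n_feat) > 1:
            raise ValueError("weak classifiers disagree on the feature universe")
        self.weak_classifiers = list(weak_classifiers)
        self.plan = plan
        self.config = config
        self.aggregation = aggregation

    @property
    def T(self) -> int:
        return len(self.weak_classifiers)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.aggregation == "mean":
            f = np.mean(
                [h.decision_function(X) for h in self.weak_classifiers], axis=0
            )
            return (f >= 0.0).astype(int)
        votes = np.sum([h.predict(X) for h in self.weak_classifiers], axis=0)
        # strict majority ceil((T+1)/2), except an exact tie at even T goes
        # positive — together that is votes >= ceil(T/2)
        needed = -(-self.T // 2)
        if self.T % 2 == 0 and np.any(votes == self.T // 2):
            logger.info("ensemble vote tie at T/2 resolved to the positive class")
        return (votes >= needed).astype(int)


def fit(
    data: ClinicalTable,
    cfg: WeightedSVMConfig = WeightedSVMConfig(),
    seed: int = 0,
    aggregation: str = "vote",
) -> EnsembleModel:
    """Algorithm: compute T from the class ratio, partition N into T
    disjoint blocks, train H_i on D_i = N_i U P, aggregate by vote.

    Training order of the T learners is irrelevant to the result; the
    partition (hence the model) is reproducible from ``seed``.
    """
    if data.n_pos == 0 or data.n_neg == 0:
        raise ValueError("both classes must be present")
    T = compute_T(data.n_neg, data.n_pos)
    neg_idx = np.flatnonzero(data.y == 0)
    pos_idx = np.flatnonzero(data.y == 1)
    plan = partition_majority(neg_idx, n_pos=len(pos_idx), T=T, seed=seed)
    learners = []
    for block in plan.subsets:
        rows = np.sort(np.concatenate([block, pos_idx]))
        learners.append(train(data.subset(rows), cfg))
    logger.info(
        "ensemble: T=%d weak learners, %d leftover majority samples",
        T, len(plan.leftover),
    )
    return EnsembleModel(learners, plan, cfg, aggregation=aggregation)


def make_ensemble_factory(
    cfg: WeightedSVMConfig = WeightedSVMConfig(), aggregation: str = "vote"
):
    """Model factory for CV; T is recomputed from each training split."""

    def factory(train_table: ClinicalTable, seed: int) -> EnsembleModel:
        return fit(train_table, cfg, seed=seed, aggregation=aggregation)

    return factory
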
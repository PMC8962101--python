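"""Confusion metrics, stratified k-fold protocol and report tables.

Evaluation is sensitivity/specificity-centric: with a 65:1 class ratio,
accuracy is meaningless (the all-negative classifier scores 98.5%), so
models are compared by per-fold Se and Sp under a shared stratified
k-fold split, with the fold mean as the headline number and the sample
variance across folds as a stability measure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data_io import ClinicalTable

logger = logging.getLogger("underbag")

DEFAULT_K = 7


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Exact TP/FN/TN/FP counts for 0/1 label vectors of equal length."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN with a warning when no positives were evaluated."""
    if c.tp + c.fn == 0:
        warnings.warn("no positive samples; sensitivity undefined", stacklevel=2)
        return float("nan")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN with a warning when no negatives were evaluated."""
    if c.tn + c.fp == 0:
        warnings.warn("no negative samples; specificity undefined", stacklevel=2)
        return float("nan")
    return c.tn / (c.tn + c.fp)


@dataclass
class CVReport:
    """Per-fold Se/Sp with mean and across-fold sample variance rows."""

    fold_se: list[float]
    fold_sp: list[float]
    k: int
    seed: int
    model: str = ""

    @property
    def mean_se(self) -> float:
        return float(np.mean(self.fold_se))

    @property
    def mean_sp(self) -> float:
        return float(np.mean(self.fold_sp))

    @property
    def var_se(self) -> float:
        """Sample variance (n-1 denominator) of Se across folds."""
        return float(np.var(self.fold_se, ddof=1))

    @property
    def var_sp(self) -> float:
        return float(np.var(self.fold_sp, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        idx = [_ordinal(i + 1) for i in range(self.k)]
        df = pd.DataFrame(
            {"Se": self.fold_se, "Sp": self.fold_sp}, index=idx
        )
        df.loc["Average"] = [self.mean_se, self.mean_sp]
        df.loc["Variance(x10^-3)"] = [self.var_se * 1e3, self.var_sp * 1e3]
        return df


def _ordinal(i: int) -> str:
    suffix = {1: "st", 2: "nd", 3: "rd"}.get(i if i < 20 else i % 10, "th")
    return f"{i}{suffix}"


def _fold_seeds(seed: int, k: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=k)]


def kfold_cv(
    data: ClinicalTable,
    model_factory,
    k: int = DEFAULT_K,
    seed: int = 0,
    model_name: str = "",
) -> CVReport:
    """Stratified k-fold cross-validation of one model factory.

    Folds preserve class proportions (remainders spread round-robin by
    the stratified splitter); the factory is called as
    ``factory(train_table, fold_seed) -> model`` with ``model.predict``,
    so any undersampling or partitioning happens inside the factory on
    training data only. Fold seeds are derived from ``seed`` and are the
    same for every model evaluated at the same (seed, k), which makes
    comparisons paired.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(data.n_pos, data.n_neg) < k:
        raise ValueError(
            f"each class needs at least k={k} samples "
            f"(|P|={data.n_pos}, |N|={data.n_neg})"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_seeds = _fold_seeds(seed, k)
    fold_se, fold_sp = [], []
    for i, (tr, te) in enumerate(splitter.split(data.X, data.y)):
        model = model_factory(data.subset(tr), fold_seeds[i])
        c = confusion(data.y[te], model.predict(data.X[te]))
        fold_se.append(sensitivity(c))
        fold_sp.append(specificity(c))
    report = CVReport(fold_se=fold_se, fold_sp=fold_sp, k=k, seed=seed,
                      model=model_name)
    logger.info(
        "%s: %d-fold CV mean Se=%.3f Sp=%.3f", model_name or "model",
        k, report.mean_se, report.mean_sp,
    )
    return report


def compare_models(
    data: ClinicalTable,
    factories: dict[str, object],
    k: int = DEFAULT_K,
    seed: int = 0,
) -> dict[str, CVReport]:
    """Evaluate several factories on identical fold assignments."""
    return {
        name: kfold_cv(data, factory, k=k, seed=seed, model_name=name)
        for name, factory in factories.items()
    }


def report_frame(reports: dict[str, CVReport]) -> pd.DataFrame:
    """Side-by-side layout: rows 1st..kth, Average, Variance(x10^-3);
    two columns (Se, Sp) per model."""
    frames = {name: rep.to_frame() for name, rep in reports.items()}
    return pd.concat(frames, axis=1)


def metadata(reports: dict[str, CVReport]) -> dict:
    """Run metadata for the JSON sidecar."""
    any_rep = next(iter(reports.values()))
    return {
        "k": any_rep.k,
        "seed": any_rep.seed,
        "models": list(reports),
    }
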
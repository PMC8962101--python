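"""Cost-sensitive kernel SVM weak learner.

The base learner minimizes a class-weighted soft-margin objective: the
hinge loss of every positive sample is multiplied by w1 and of every
negative sample by w2, so raising w1 makes missed cases more expensive
and pushes the decision boundary toward the majority class. In penalty
form the objective per sample-weight c_i is

    sum_i c_i [1 - y_i f(x_i)]_+  +  lambda ||f||^2,   lambda = 1 / (2 C),

equivalent to the usual C-parameterized SVM with per-class box constraints
0 <= alpha_i <= C * c_i. Features are z-scored internally (fitted on the
training data only) because an RBF width of gamma = 0.004 on raw clinical
units would be dominated by the largest-scale features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_io import ClinicalTable

logger = logging.getLogger("underbag")


@dataclass(frozen=True)
class WeightedSVMConfig:
    """Base-learner hyperparameters.

    Defaults follow the screening-model setting: RBF kernel, C = 4,
    gamma = 0.004, positive-class weight w1 = 1.3, negative-class weight
    w2 = 1. ``degree`` is unused for the RBF kernel and carried only for
    config parity.
    """

    kernel: str = "rbf"
    C: float = 4.0
    gamma: float = 0.004
    degree: int = 3
    w1: float = 1.3
    w2: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("class weights must be positive")

    @property
    def lambda_(self) -> float:
        """Regularization weight of the penalty-form objective."""
        return 1.0 / (2.0 * self.C)

    def with_weights(self, w1: float, w2: float) -> "WeightedSVMConfig":
        return replace(self, w1=w1, w2=w2)


#: Weight settings of the cost-sensitivity study; (w1, w2) with w1 <= 2
#: because heavier positive weighting drives specificity too low.
DEFAULT_WEIGHT_GRID: tuple[tuple[float, float], ...] = (
    (1.0, 1.0), (1.3, 1.0), (1.6, 1.0), (2.0, 1.0),
)


def weighted_hinge_objective(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, cfg: WeightedSVMConfig
) -> float:
    """Penalty-form objective for a *linear* decision function f(x) = w.x + b.

    sum_i c_i [1 - y_i f(x_i)]_+ + lambda ||w||^2 with c_i = w1 for
    positives (label 1) and w2 for negatives, lambda = 1/(2C). Test
    oracle; the production solver path is :func:`train`.
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    y_signed = np.where(np.asarray(y) == 1, 1.0, -1.0)
    c = np.where(np.asarray(y) == 1, cfg.w1, cfg.w2)
    margins = 1.0 - y_signed * (X @ w + b)
    hinge = float(np.sum(c * np.maximum(margins, 0.0)))
    return hinge + cfg.lambda_ * float(w @ w)


class WeakClassifier:
    """A trained cost-sensitive SVM with its training-time scaler.

    ``decision_function`` returns f(x); ``predict`` labels a sample 1 when
    f(x) >= 0 (the exact tie goes to the positive class — screening
    favors sensitivity).
    """

    def __init__(self, svc: SVC, scaler: StandardScaler | None, cfg: WeightedSVMConfig):
        self._svc = svc
        self._scaler = scaler
        self.config = cfg

    @property
    def n_features(self) -> int:
        return int(self._svc.n_features_in_)

    @property
    def dual_coef_(self) -> np.ndarray:
        """Signed dual coefficients alpha_i * y_i of the support vectors."""
        return self._svc.dual_coef_

    @property
    def support_labels_(self) -> np.ndarray:
        return np.where(self._svc.dual_coef_.ravel() > 0, 1, 0)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got shape {X.shape}"
            )
        return self._scaler.transform(X) if self._scaler is not None else X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self._transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(int)

    def linear_parameters(self) -> tuple[np.ndarray, float]:
        """(w, b) of a linear-kernel model, in the internal (scaled) space."""
        if self.config.kernel != "linear":
            raise ValueError("linear parameters only exist for the linear kernel")
        return self._svc.coef_.ravel().copy(), float(self._svc.intercept_[0])


def train(data: ClinicalTable, cfg: WeightedSVMConfig) -> WeakClassifier:
    """Fit the cost-sensitive SVM on a table containing both classes.

    The dual solution satisfies the class-weighted box constraints
    0 <= alpha_i <= C * w1 (positives) / C * w2 (negatives); z-scoring is
    fitted on this training data only.
    """
    if data.n_pos == 0 or data.n_neg == 0:
        raise ValueError("training data must contain both classes")
    X = data.X
    scaler = None
    if cfg.standardize:
        scaler = StandardScaler()
        X = scaler.fit_transform(X)
        # constant columns get scale 0 -> transform would divide by ~0; sklearn
        # already maps zero variance to scale 1, nothing extra needed
    svc = SVC(
        kernel=cfg.kernel,
        C=cfg.C,
        gamma=cfg.gamma,
        degree=cfg.degree,
        class_weight={1: cfg.w1, 0: cfg.w2},
        tol=1e-4,
    )
    svc.fit(X, data.y)
    return WeakClassifier(svc, scaler, cfg)


@dataclass
class WeightGridReport:
    """Cross-validated Se/Sp for each class-weight setting.

    ``reports`` maps the setting label "SVM (w1, w2)" to its CVReport;
    :meth:`to_frame` lays the fold rows out side by side.
    """

    settings: list[tuple[float, float]]
    reports: dict[str, "CVReport"] = field(default_factory=dict)

    @staticmethod
    def label(w1: float, w2: float) -> str:
        return f"SVM ({w1:g}, {w2:g})"

    def average(self, w1: float, w2: float) -> tuple[float, float]:
        rep = self.reports[self.label(w1, w2)]
        return rep.mean_se, rep.mean_sp

    def to_frame(self) -> pd.DataFrame:
        from .evaluate import report_frame

        return report_frame(self.reports)


def make_single_svm_factory(
    cfg: WeightedSVMConfig, undersample: bool = True
):
    """Model factory for CV: optionally random-undersample the majority
    class of the training split to |P| before fitting one weighted SVM."""

    def factory(train_table: ClinicalTable, seed: int) -> WeakClassifier:
        table = train_table
        if undersample:
            rng = np.random.default_rng(seed)
            neg_idx = np.flatnonzero(table.y == 0)
            pos_idx = np.flatnonzero(table.y == 1)
            keep_neg = rng.choice(neg_idx, size=len(pos_idx), replace=False)
            rows = np.sort(np.concatenate([pos_idx, keep_neg]))
            table = table.subset(rows)
        return train(table, cfg)

    return factory


def weight_grid(
    data: ClinicalTable,
    grid: tuple[tuple[float, float], ...] = DEFAULT_WEIGHT_GRID,
    k: int = 7,
    seed: int = 0,
    cfg: WeightedSVMConfig = WeightedSVMConfig(),
    undersample: bool = True,
) -> WeightGridReport:
    """Cross-validate one undersampled weighted SVM per grid setting.

    All settings share identical fold splits and identical per-fold
    undersampling seeds, so they differ only in the class weights.
    """
    from .evaluate import compare_models

    factories = {
        WeightGridReport.label(w1, w2): make_single_svm_factory(
            cfg.with_weights(w1, w2), undersample=undersample
        )
        for (w1, w2) in grid
    }
    reports = compare_models(data, factories, k=k, seed=seed)
    return WeightGridReport(settings=list(grid), reports=reports)
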
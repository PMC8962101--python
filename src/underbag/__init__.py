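"""underbag: cost-sensitive SVM underbagging for severely imbalanced
clinical screening tables.

Pipeline: load/clean a mixed-type clinical table (`data_io`), screen
features by significance tests plus a multivariable logistic model and
keep the union (`featselect`), train class-weighted kernel SVM weak
learners (`wsvm`), bag them over a disjoint partition of the majority
class (`ensemble`), and report per-fold sensitivity/specificity under
stratified cross-validation (`evaluate`). `synthetic` generates
imbalanced cohorts with controlled overlap for testing and benchmarking.
"""

from . import data_io, ensemble, evaluate, featselect, reference, synthetic, wsvm
from .data_io import (
    ClinicalTable,
    CleanReport,
    FeatureSpec,
    drop_missing,
    imbalance_ratio,
    load_table,
    write_table,
)
from .ensemble import EnsembleModel, PartitionPlan, compute_T, partition_majority
from .evaluate import (
    ConfusionCounts,
    CVReport,
    compare_models,
    confusion,
    kfold_cv,
    report_frame,
    sensitivity,
    specificity,
)
from .featselect import (
    ContingencyTable2x2,
    FeatureSets,
    GroupSummary,
    LogisticFit,
    SignificanceResult,
    chi_square_test,
    fit_logistic,
    select_features,
    significance_screen,
    t_test,
)
from .synthetic import SimSpec, generate, make_worked_fixture, benchmark_spec
from .wsvm import (
    DEFAULT_WEIGHT_GRID,
    WeakClassifier,
    WeightedSVMConfig,
    WeightGridReport,
    make_single_svm_factory,
    train,
    weight_grid,
    weighted_hinge_objective,
)

__version__ = "0.1.0"

fit_ensemble = ensemble.fit

__all__ = [
    "ClinicalTable", "CleanReport", "FeatureSpec", "load_table", "write_table",
    "drop_missing", "imbalance_ratio",
    "SimSpec", "generate", "benchmark_spec", "make_worked_fixture",
    "ContingencyTable2x2", "GroupSummary", "SignificanceResult", "LogisticFit",
    "FeatureSets", "chi_square_test", "t_test", "significance_screen",
    "fit_logistic", "select_features",
    "WeightedSVMConfig", "WeakClassifier", "WeightGridReport", "train",
    "weighted_hinge_objective", "weight_grid", "make_single_svm_factory",
    "DEFAULT_WEIGHT_GRID",
    "compute_T", "partition_majority", "PartitionPlan", "EnsembleModel",
    "fit_ensemble",
    "ConfusionCounts", "confusion", "sensitivity", "specificity", "CVReport",
    "kfold_cv", "compare_models", "report_frame",
    "reference",
]
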
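"""Shared fixtures: the hard-coded worked example and the seeded 65:1
synthetic benchmark cohort (expensive results are session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

import underbag as ub

BENCHMARK_SEED = 1
VARIANCE_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def worked():
    return ub.make_worked_fixture()


@pytest.fixture(scope="session")
def benchmark_table():
    """120 cases vs 7,800 controls (65:1), mixed weak-effect features."""
    table, truth = ub.generate(ub.benchmark_spec(seed=BENCHMARK_SEED))
    return table, truth


@pytest.fixture(scope="session")
def benchmark_grid(benchmark_table):
    """Seven-fold CV of the single undersampled SVM across the weight grid."""
    table, _ = benchmark_table
    return ub.weight_grid(table, k=7, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_compare(benchmark_table):
    """Paired 7-fold comparison: ensemble vs single SVMs on shared folds."""
    table, _ = benchmark_table
    return ub.compare_models(
        table,
        {
            "ensemble": ub.ensemble.make_ensemble_factory(ub.WeightedSVMConfig()),
            "svm_unweighted": ub.make_single_svm_factory(
                ub.WeightedSVMConfig().with_weights(1.0, 1.0)
            ),
            "svm_weighted": ub.make_single_svm_factory(ub.WeightedSVMConfig()),
        },
        k=7,
        seed=BENCHMARK_SEED,
    )


@pytest.fixture(scope="session")
def ten_seed_variances(benchmark_table):
    """Across-fold Se variances of ensemble vs single undersampled weighted
    SVM, repeated over ten CV seeds (bagging variance-reduction study)."""
    table, _ = benchmark_table
    ens, single = [], []
    for seed in VARIANCE_SEEDS:
        reports = ub.compare_models(
            table,
            {
                "ens": ub.ensemble.make_ensemble_factory(ub.WeightedSVMConfig()),
                "svm": ub.make_single_svm_factory(ub.WeightedSVMConfig()),
            },
            k=7,
            seed=seed,
        )
        ens.append(reports["ens"].var_se)
        single.append(reports["svm"].var_se)
    return np.asarray(ens), np.asarray(single)
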
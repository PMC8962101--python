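"""Synthetic imbalanced clinical-like tables.

The generator emulates the regime of a severely imbalanced in-patient
screening cohort: a 65:1 majority-to-minority ratio, a mixed panel of
continuous laboratory values and binary history/presentation indicators,
and heavy class overlap — per-feature standardized mean differences small
enough that no single feature separates cases from controls. Continuous
features are class-conditional Gaussians with unit variance; binary
features are class-conditional Bernoullis. Only a subset of features is
genuinely informative; the rest have exactly zero effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ClinicalTable, FeatureSpec

#: Default control-group success probability for binary indicators.
DEFAULT_BINARY_BASE_RATE = 0.3

#: Ranges the default effect sizes are drawn from (once per seed):
#: standardized mean differences for continuous features, probability gaps
#: for binary indicators (matching the small case/control frequency gaps
#: typical of clinical presentation variables).
CONTINUOUS_EFFECT_RANGE = (0.1, 0.6)
BINARY_EFFECT_RANGE = (0.05, 0.15)


@dataclass
class SimSpec:
    """Specification of one synthetic cohort.

    Defaults give the scaled-down benchmark used throughout: 120 cases vs
    7,800 controls (ratio 65:1), 16 continuous + 8 binary features, half of
    them informative with weak effects.
    """

    n_pos: int = 120
    n_neg: int = 7800
    p_continuous: int = 16
    p_binary: int = 8
    informative_fraction: float = 0.5
    effect_sizes: dict[str, float] | None = None
    binary_base_rate: float = DEFAULT_BINARY_BASE_RATE
    equicorrelation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2:
            raise ValueError("n_pos must be >= 2")
        if self.n_neg < self.n_pos:
            raise ValueError("n_neg must be >= n_pos (positives are the minority)")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must be in [0, 1]")
        if not 0.0 <= self.equicorrelation < 1.0:
            raise ValueError("equicorrelation must be in [0, 1)")

    @property
    def feature_names(self) -> list[str]:
        return [f"lab_{j:02d}" for j in range(self.p_continuous)] + [
            f"ind_{j:02d}" for j in range(self.p_binary)
        ]


def _default_effects(spec: SimSpec, rng: np.random.Generator) -> dict[str, float]:
    names = spec.feature_names
    p = len(names)
    k = int(round(spec.informative_fraction * p))
    informative = rng.choice(p, size=k, replace=False)
    effects = {name: 0.0 for name in names}
    for j in informative:
        name = names[j]
        lo, hi = (
            CONTINUOUS_EFFECT_RANGE if j < spec.p_continuous else BINARY_EFFECT_RANGE
        )
        effects[name] = float(rng.uniform(lo, hi))
    return effects


def generate(spec: SimSpec) -> tuple[ClinicalTable, dict]:
    """Generate a table per ``spec``; identical spec+seed gives identical output.

    Returns the table and a ground-truth record
    ``{"informative": [...], "effect_sizes": {...}}``.
    """
    rng = np.random.default_rng(spec.seed)
    effects = spec.effect_sizes
    if effects is None:
        effects = _default_effects(spec, rng)
    names = spec.feature_names
    missing = set(names) - set(effects)
    if missing:
        raise ValueError(f"effect_sizes missing entries for {sorted(missing)}")

    n = spec.n_pos + spec.n_neg
    y = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    cols = []
    specs: list[FeatureSpec] = []
    rho = spec.equicorrelation
    shared = rng.standard_normal(n) if rho > 0 else None
    for j, name in enumerate(names):
        d = effects[name]
        if j < spec.p_continuous:
            z = rng.standard_normal(n)
            if shared is not None:
                z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z
            col = z + np.where(y == 1, d, 0.0)
            specs.append(FeatureSpec(name=name, kind="continuous"))
        else:
            p0 = spec.binary_base_rate
            p1 = p0 + d
            if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
                raise ValueError(
                    f"probability gap {d} pushes Bernoulli parameter for "
                    f"{name!r} outside [0, 1]"
                )
            col = (rng.random(n) < np.where(y == 1, p1, p0)).astype(float)
            specs.append(FeatureSpec(name=name, kind="categorical"))
        cols.append(col)

    X = np.column_stack(cols)
    order = rng.permutation(n)
    table = ClinicalTable(features=specs, X=X[order], y=y[order])
    truth = {
        "informative": sorted(k for k, v in effects.items() if v != 0.0),
        "effect_sizes": dict(effects),
        "seed": spec.seed,
    }
    return table, truth


def benchmark_spec(seed: int = 0, **overrides) -> SimSpec:
    """The default 65:1 benchmark cohort specification."""
    return SimSpec(seed=seed, **overrides)


# 12-subject worked example: 9 controls, 3 cases, two lab values and one
# binary indicator. Used throughout the unit tests and documentation.
_WORKED_ROWS = [
    # (lab_a, lab_b, ind_a, label)
    (5.1, 1.2, 0, 0),
    (4.8, 0.9, 0, 0),
    (5.6, 1.1, 1, 0),
    (4.2, 1.4, 0, 0),
    (5.0, 1.0, 0, 0),
    (5.3, 0.8, 1, 0),
    (4.6, 1.3, 0, 0),
    (5.2, 1.1, 0, 0),
    (4.9, 1.2, 1, 0),
    (6.4, 1.6, 1, 1),
    (6.1, 1.5, 0, 1),
    (6.8, 1.7, 1, 1),
]


def make_worked_fixture() -> ClinicalTable:
    """Fixed 12-row, 3-feature table: |N| = 9, |P| = 3 (ratio 3:1)."""
    rows = np.asarray(_WORKED_ROWS, dtype=float)
    return ClinicalTable(
        features=[
            FeatureSpec("lab_a", "continuous", group="biochemical"),
            FeatureSpec("lab_b", "continuous", group="blood_routine"),
            FeatureSpec("ind_a", "categorical", group="other"),
        ],
        X=rows[:, :3],
        y=rows[:, 3].astype(int),
    )
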
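"""Two-screen feature selection with a union rule.

Candidate features pass through two independent screens:

* a significance screen ``Fs`` — Pearson chi-square (no continuity
  correction) for binary indicators, pooled-variance Student's t for
  continuous features, both against a 0.05 threshold;
* a multivariable logistic screen ``Fl`` — one unpenalized maximum-
  likelihood logistic model over all candidates, Wald p per coefficient.

The selected set is the union ``Fset = Fs | Fl``. The two screens are
deliberately permissive (no multiple-testing correction): the goal is not
inference but discarding clearly uninformative columns before training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ClinicalTable

logger = logging.getLogger("underbag")

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a (case & exposed), b (case & unexposed), c (control &
    exposed), d (control & unexposed)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class GroupSummary:
    """Per-class sample size, mean and SD of one continuous feature."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class SignificanceResult:
    feature: str
    test: str  # "chi_square" | "t_test"
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class LogisticFit:
    """One coefficient row of the multivariable logistic model."""

    feature: str
    B: float
    standard_error: float
    odds_ratio: float
    ci95: tuple[float, float]
    wald_p: float
    converged: bool = True
    separation_flag: bool = False


@dataclass(frozen=True)
class FeatureSets:
    """The two screens and their union; invariant Fset == Fs | Fl."""

    Fs: frozenset[str]
    Fl: frozenset[str]
    Fset: frozenset[str]

    def __post_init__(self) -> None:
        if self.Fset != self.Fs | self.Fl:
            raise ValueError("Fset must equal Fs union Fl")

    @property
    def overlap_report(self) -> dict[str, int]:
        return {
            "n_Fs": len(self.Fs),
            "n_Fl": len(self.Fl),
            "n_overlap": len(self.Fs & self.Fl),
            "n_Fset": len(self.Fset),
        }


def chi_square_test(t: ContingencyTable2x2, feature: str = "") -> SignificanceResult:
    """Pearson chi-square on a 2x2 table, without continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), p from the upper tail
    of chi-square with 1 df. A zero margin makes the statistic undefined;
    it is reported as 0 with p = 1 and the degenerate flag set.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        return SignificanceResult(feature, "chi_square", 0.0, 1.0, degenerate=True)
    chi2 = t.total * (a * d - b * c) ** 2 / np.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return SignificanceResult(feature, "chi_square", float(chi2), p)


def t_test(g: GroupSummary, feature: str = "") -> SignificanceResult:
    """Pooled-variance two-sample Student's t from group summaries.

    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    t = (mean1 - mean2) / (sp sqrt(1/n1 + 1/n2)); two-sided p with
    n1+n2-2 degrees of freedom.
    """
    df = g.n1 + g.n2 - 2
    sp2 = ((g.n1 - 1) * g.sd1**2 + (g.n2 - 1) * g.sd2**2) / df
    diff = g.mean1 - g.mean2
    if sp2 == 0:
        if diff == 0:
            return SignificanceResult(feature, "t_test", 0.0, 1.0, degenerate=True)
        t = np.inf if diff > 0 else -np.inf
        return SignificanceResult(feature, "t_test", float(t), 0.0, degenerate=True)
    t = diff / np.sqrt(sp2 * (1.0 / g.n1 + 1.0 / g.n2))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return SignificanceResult(feature, "t_test", float(t), p)


def group_summary(x: np.ndarray, y: np.ndarray) -> GroupSummary:
    """Summaries of a continuous feature per class (class 1 first)."""
    x1, x2 = x[y == 1], x[y == 0]
    return GroupSummary(
        n1=len(x1), mean1=float(np.mean(x1)), sd1=float(np.std(x1, ddof=1)),
        n2=len(x2), mean2=float(np.mean(x2)), sd2=float(np.std(x2, ddof=1)),
    )


def contingency_2x2(x: np.ndarray, y: np.ndarray) -> ContingencyTable2x2:
    """Cross-tabulate a 0/1 feature against the 0/1 label."""
    x = np.asarray(x).astype(int)
    return ContingencyTable2x2(
        a=int(np.sum((y == 1) & (x == 1))),
        b=int(np.sum((y == 1) & (x == 0))),
        c=int(np.sum((y == 0) & (x == 1))),
        d=int(np.sum((y == 0) & (x == 0))),
    )


def significance_screen(table: ClinicalTable) -> list[SignificanceResult]:
    """Per-feature univariate test: chi-square for categoricals, pooled t
    for continuous features."""
    results = []
    for j, spec in enumerate(table.features):
        x = table.X[:, j]
        if spec.kind == "categorical":
            results.append(chi_square_test(contingency_2x2(x, table.y), spec.name))
        else:
            results.append(t_test(group_summary(x, table.y), spec.name))
    return results


_SEPARATION_SE = 50.0  # Wald SE beyond which a coefficient is treated as runaway


def fit_logistic(table: ClinicalTable, maxiter: int = 100) -> list[LogisticFit]:
    """One multivariable logistic model over all candidate features.

    Unpenalized maximum likelihood via iteratively reweighted least
    squares, intercept included. Constant features are dropped with a
    warning. Quasi-separation (runaway coefficient with an enormous Wald
    SE, or a binary feature with a zero cell against the label) and
    non-convergence set flags instead of raising; flagged features keep
    their Wald p as computed.
    """
    import statsmodels.api as sm

    keep_idx = []
    for j, spec in enumerate(table.features):
        if np.ptp(table.X[:, j]) == 0:
            warnings.warn(
                f"dropping constant feature {spec.name!r} from logistic screen",
                stacklevel=2,
            )
        else:
            keep_idx.append(j)
    if table.n_pos < 2 or table.n_neg < 2:
        raise ValueError("logistic screen needs >= 2 samples per class")

    X = sm.add_constant(table.X[:, keep_idx], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(table.y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=maxiter)
    converged = bool(getattr(res, "converged", True))

    fits: list[LogisticFit] = []
    for pos, j in enumerate(keep_idx, start=1):  # skip intercept at 0
        spec = table.features[j]
        B = float(res.params[pos])
        se = float(res.bse[pos])
        zero_cell = False
        if spec.kind == "categorical":
            t = contingency_2x2(table.X[:, j], table.y)
            zero_cell = min(t.a, t.b, t.c, t.d) == 0
        sep = zero_cell or not np.isfinite(se) or se > _SEPARATION_SE
        wald_p = float(2.0 * stats.norm.sf(abs(B / se))) if se > 0 else 1.0
        with np.errstate(over="ignore"):  # runaway SE under separation -> inf CI
            ci = (float(np.exp(B - 1.96 * se)), float(np.exp(B + 1.96 * se)))
        fits.append(
            LogisticFit(
                feature=spec.name,
                B=B,
                standard_error=se,
                odds_ratio=float(np.exp(B)),
                ci95=ci,
                wald_p=wald_p,
                converged=converged,
                separation_flag=bool(sep),
            )
        )
    return fits


def select_features(
    sig: list[SignificanceResult],
    logi: list[LogisticFit],
    alpha: float = DEFAULT_ALPHA,
) -> FeatureSets:
    """Union selection rule: Fs = {p_sig <= alpha}, Fl = {p_wald <= alpha},
    Fset = Fs | Fl. Requires the same feature universe in both inputs."""
    sig_names = {r.feature for r in sig}
    logi_names = {r.feature for r in logi}
    if sig_names != logi_names:
        raise ValueError(
            "feature universes differ between the significance and logistic "
            f"screens: {sorted(sig_names ^ logi_names)}"
        )
    Fs = frozenset(r.feature for r in sig if r.p_value <= alpha)
    Fl = frozenset(r.feature for r in logi if r.wald_p <= alpha)
    sets = FeatureSets(Fs=Fs, Fl=Fl, Fset=Fs | Fl)
    logger.info("feature selection: %s", sets.overlap_report)
    return sets


def results_frame(
    sig: list[SignificanceResult], logi: list[LogisticFit]
) -> pd.DataFrame:
    """Combined per-feature results table (one row per feature)."""
    s = pd.DataFrame([r.__dict__ for r in sig]).set_index("feature")
    l = pd.DataFrame([r.__dict__ for r in logi]).set_index("feature")
    l[["ci95_low", "ci95_high"]] = pd.DataFrame(l.pop("ci95").tolist(), index=l.index)
    return s.join(l, how="outer")
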
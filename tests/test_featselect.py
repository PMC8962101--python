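"""Two-screen feature selection: tests against published statistics and
independent oracles (scipy cross-checks, permutation null, closed forms)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import underbag as ub
from underbag import reference as ref
from underbag.featselect import contingency_2x2, group_summary


class TestChiSquare:
    def test_published_counts_reproduced(self):
        chest = ub.chi_square_test(ref.CHEST_PAIN_TABLE)
        assert chest.statistic == pytest.approx(ref.CHEST_PAIN_CHI2, abs=0.01)
        sex = ub.chi_square_test(ref.SEX_TABLE)
        assert sex.statistic == pytest.approx(ref.SEX_CHI2, abs=0.01)
        assert chest.p_value < 0.001 and sex.p_value < 0.001

    def test_independence_gives_zero(self):
        r = ub.chi_square_test(ub.ContingencyTable2x2(10, 10, 10, 10))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ub.ContingencyTable2x2(-1, 2, 3, 4)

    def test_zero_margin_degenerate(self):
        r = ub.chi_square_test(ub.ContingencyTable2x2(0, 0, 5, 7))
        assert r.degenerate and r.statistic == 0.0 and r.p_value == 1.0

    @pytest.mark.parametrize("a,b,c,d", [(12, 5, 9, 20), (3, 17, 11, 2), (40, 1, 2, 30)])
    def test_row_swap_and_transpose_invariance(self, a, b, c, d):
        base = ub.chi_square_test(ub.ContingencyTable2x2(a, b, c, d)).statistic
        swapped = ub.chi_square_test(ub.ContingencyTable2x2(c, d, a, b)).statistic
        transposed = ub.chi_square_test(ub.ContingencyTable2x2(a, c, b, d)).statistic
        assert base == pytest.approx(swapped, rel=1e-12)
        assert base == pytest.approx(transposed, rel=1e-12)

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 60, size=4)
            mine = ub.chi_square_test(ub.ContingencyTable2x2(a, b, c, d))
            chi2, p, _, _ = stats.chi2_contingency(
                np.array([[a, b], [c, d]]), correction=False
            )
            assert mine.statistic == pytest.approx(chi2, rel=1e-10)
            assert mine.p_value == pytest.approx(p, rel=1e-10)

    def test_p_value_agrees_with_permutation_null(self):
        # permutation null of a 2x2 with fixed margins is hypergeometric in
        # a; the statistic is discrete with an atom at the observed value,
        # so the continuous chi-square tail is compared against the mid-P
        # (half the boundary atom), the standard discreteness adjustment
        table = ub.ContingencyTable2x2(14, 16, 9, 31)
        obs = ub.chi_square_test(table).statistic
        rng = np.random.default_rng(0)
        n_draws = 10_000
        row1 = table.a + table.b
        col1 = table.a + table.c
        total = table.total
        a_sim = rng.hypergeometric(col1, total - col1, row1, size=n_draws)
        stats_sim = np.array([
            ub.chi_square_test(
                ub.ContingencyTable2x2(int(a), row1 - int(a),
                                       col1 - int(a), total - row1 - col1 + int(a))
            ).statistic
            for a in a_sim
        ])
        p_mc = (np.mean(stats_sim > obs + 1e-9)
                + 0.5 * np.mean(np.abs(stats_sim - obs) < 1e-9))
        mc_se = np.sqrt(p_mc * (1 - p_mc) / n_draws)
        p_asym = ub.chi_square_test(table).p_value
        assert abs(p_asym - p_mc) <= 2 * mc_se


class TestTTest:
    def test_published_summary_reproduced(self):
        r = ub.t_test(ref.NEUT_SUMMARY)
        assert r.statistic == pytest.approx(ref.NEUT_T, abs=0.1)

    def test_identical_groups(self):
        g = ub.GroupSummary(10, 5.0, 1.0, 10, 5.0, 1.0)
        r = ub.t_test(g)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_antisymmetric_in_group_order(self):
        g = ub.GroupSummary(12, 3.1, 0.8, 20, 2.4, 1.1)
        fwd = ub.t_test(g)
        rev = ub.t_test(ub.GroupSummary(20, 2.4, 1.1, 12, 3.1, 0.8))
        assert fwd.statistic == pytest.approx(-rev.statistic, rel=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)

    def test_zero_variance_cases(self):
        same = ub.t_test(ub.GroupSummary(5, 2.0, 0.0, 5, 2.0, 0.0))
        assert same.statistic == 0.0 and same.p_value == 1.0
        apart = ub.t_test(ub.GroupSummary(5, 3.0, 0.0, 5, 2.0, 0.0))
        assert np.isinf(apart.statistic) and apart.p_value == 0.0

    def test_matches_raw_data_computation(self):
        # summary-based pooled t equals scipy's from-raw equal-variance t
        x1 = np.array([4.1, 5.3, 6.0])
        x2 = np.array([3.2, 3.9, 2.8])
        g = ub.GroupSummary(
            3, float(np.mean(x1)), float(np.std(x1, ddof=1)),
            3, float(np.mean(x2)), float(np.std(x2, ddof=1)),
        )
        mine = ub.t_test(g)
        t_sp, p_sp = stats.ttest_ind(x1, x2, equal_var=True)
        assert mine.statistic == pytest.approx(t_sp, rel=1e-10)
        assert mine.p_value == pytest.approx(p_sp, rel=1e-10)


class TestSignificanceScreen:
    def test_dispatch_by_kind(self, worked):
        results = {r.feature: r for r in ub.significance_screen(worked)}
        assert results["lab_a"].test == "t_test"
        assert results["ind_a"].test == "chi_square"

    def test_continuous_screen_matches_manual_summaries(self, worked):
        res = {r.feature: r for r in ub.significance_screen(worked)}
        g = group_summary(worked.X[:, 0], worked.y)
        assert res["lab_a"].statistic == pytest.approx(
            ub.t_test(g).statistic, rel=1e-12
        )


class TestLogistic:
    def _binary_table(self, a, b, c, d):
        x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        y = np.concatenate([np.ones(a + b, int), np.zeros(c + d, int)])
        return ub.ClinicalTable(
            features=[ub.FeatureSpec("expo", "categorical")],
            X=x.reshape(-1, 1), y=y,
        )

    def test_univariate_binary_equals_log_odds_ratio(self):
        a, b, c, d = 30, 20, 10, 40
        fits = ub.fit_logistic(self._binary_table(a, b, c, d))
        closed_form = np.log((a * d) / (b * c))
        assert fits[0].B == pytest.approx(closed_form, abs=1e-6)
        assert fits[0].odds_ratio == pytest.approx(np.exp(closed_form), rel=1e-6)

    def test_or_and_ci_transforms(self):
        fits = ub.fit_logistic(self._binary_table(25, 25, 15, 35))
        f = fits[0]
        assert f.odds_ratio == pytest.approx(np.exp(f.B), rel=1e-12)
        lo, hi = f.ci95
        assert lo <= f.odds_ratio <= hi

    def test_published_exp_transforms(self):
        assert np.exp(ref.CHEST_PAIN_B) == pytest.approx(ref.CHEST_PAIN_OR, abs=1e-3)
        assert np.exp(ref.AORTIC_MURMUR_B) == pytest.approx(
            ref.AORTIC_MURMUR_OR, abs=1e-3
        )

    def test_separation_flagged_not_raised(self):
        # zero exposed cases: quasi-separation, like a family-history
        # indicator with no events among cases
        fits = ub.fit_logistic(self._binary_table(0, 50, 5, 45))
        assert fits[0].separation_flag
        assert fits[0].B < 0  # runaway negative coefficient

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=40), np.full(40, 7.0)])
        y = (rng.random(40) < 0.4).astype(int)
        y[:2] = [0, 1]  # both classes present
        t = ub.ClinicalTable(
            features=[ub.FeatureSpec("ok"), ub.FeatureSpec("const")], X=X, y=y
        )
        with pytest.warns(UserWarning, match="constant"):
            fits = ub.fit_logistic(t)
        assert [f.feature for f in fits] == ["ok"]

    def test_multivariable_matches_statsmodels_logit(self):
        # same model through the independent Logit (Newton) path
        import statsmodels.api as sm

        table, _ = ub.generate(
            ub.SimSpec(n_pos=80, n_neg=400, p_continuous=3, p_binary=2, seed=9)
        )
        fits = ub.fit_logistic(table)
        X = sm.add_constant(table.X)
        res = sm.Logit(table.y, X).fit(disp=0)
        for j, f in enumerate(fits, start=1):
            assert f.B == pytest.approx(res.params[j], abs=1e-5)


def mock_screen_inputs(n_sig_only, n_both, n_logi_only, n_neither):
    """Screen results realizing given set cardinalities via p-values."""
    names = [f"f{i}" for i in range(n_sig_only + n_both + n_logi_only + n_neither)]
    in_fs = set(names[: n_sig_only + n_both])
    in_fl = set(names[n_sig_only : n_sig_only + n_both + n_logi_only])
    sig = [
        ub.SignificanceResult(n, "t_test", 1.0, 0.01 if n in in_fs else 0.5)
        for n in names
    ]
    logi = [
        ub.LogisticFit(n, 0.1, 0.1, 1.1, (1.0, 1.2),
                       0.01 if n in in_fl else 0.5)
        for n in names
    ]
    return sig, logi


class TestSelectFeatures:
    _mock_inputs = staticmethod(mock_screen_inputs)

    def test_published_cardinalities(self):
        # |Fs| = 49, |Fl| = 35, overlap 26 -> |Fset| = 58 out of 71 candidates
        sig, logi = self._mock_inputs(23, 26, 9, 13)
        sets = ub.select_features(sig, logi)
        assert sets.overlap_report == {
            "n_Fs": ref.N_FS, "n_Fl": ref.N_FL,
            "n_overlap": ref.N_OVERLAP, "n_Fset": ref.N_FSET,
        }

    def test_all_insignificant_gives_empty_set(self):
        sig, logi = self._mock_inputs(0, 0, 0, 10)
        sets = ub.select_features(sig, logi)
        assert sets.Fset == frozenset()

    def test_subset_absorption(self):
        sig, logi = self._mock_inputs(5, 3, 0, 2)  # Fl subset of Fs
        sets = ub.select_features(sig, logi)
        assert sets.Fl <= sets.Fs and sets.Fset == sets.Fs

    def test_threshold_is_inclusive(self):
        sig = [ub.SignificanceResult("f", "t_test", 2.0, 0.05)]
        logi = [ub.LogisticFit("f", 0.1, 0.1, 1.1, (1.0, 1.2), 0.5)]
        assert "f" in ub.select_features(sig, logi).Fs

    def test_mismatched_universes_rejected(self):
        sig, logi = self._mock_inputs(1, 1, 1, 0)
        with pytest.raises(ValueError, match="universes"):
            ub.select_features(sig, logi[:-1])

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                    min_size=0, max_size=60))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_inclusion_exclusion_property(self, pvals):
        sig = [ub.SignificanceResult(f"f{i}", "t_test", 1.0, ps)
               for i, (ps, _) in enumerate(pvals)]
        logi = [ub.LogisticFit(f"f{i}", 0.1, 0.1, 1.1, (1.0, 1.2), pl)
                for i, (_, pl) in enumerate(pvals)]
        sets = ub.select_features(sig, logi)
        assert sets.Fset == sets.Fs | sets.Fl
        assert len(sets.Fset) == len(sets.Fs) + len(sets.Fl) - len(sets.Fs & sets.Fl)
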
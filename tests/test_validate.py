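"""Diagnostic metrics, Wald CIs and 2x2 association tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, hypergeom

from breathprint import (
    ConfusionMatrix,
    SimulationConfig,
    confusion_metrics,
    external_validate,
    fisher_exact,
    fit_model,
    mantel_haenszel_chi2,
    pearson_chi2,
    simulate_breathprints,
    t_test_from_summary,
    wald_ci,
    yates_chi2,
)

# confusion matrices of the two frozen training models on a 9 vs 8 validation
# cohort, reconstructed from the printed sensitivity/specificity
CM_A = ConfusionMatrix(tp=7, fn=2, fp=4, tn=4)
CM_B = ConfusionMatrix(tp=6, fn=3, fp=4, tn=4)


def random_tables(n_tables, rng, max_cell=12):
    for _ in range(n_tables):
        a, b, c, d = rng.integers(0, max_cell + 1, size=4)
        if a + b + c + d == 0:
            a = 1
        yield ConfusionMatrix(tp=int(a), fn=int(b), fp=int(c), tn=int(d))


class TestWaldCI:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            ((11), 17, (42.0, 87.4)),
            (4, 6, (28.9, 100.0)),
            (0, 10, (0.0, 0.0)),
            (10, 10, (100.0, 100.0)),
            (7, 11, (35.2, 92.1)),
            (4, 7, (20.5, 93.8)),
        ],
    )
    def test_frozen_values(self, k, n, expected):
        assert wald_ci(k, n) == expected

    @given(st.integers(0, 60), st.integers(1, 60))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_interval_contains_proportion(self, k, n):
        k = min(k, n)
        low, high = wald_ci(k, n)
        p = 100.0 * k / n
        assert low <= p + 0.05 and p - 0.05 <= high
        assert 0.0 <= low <= high <= 100.0

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (10, 100, 1000):
            k = n // 2
            low, high = wald_ci(k, n)
            widths.append(high - low)
        assert widths[0] > widths[1] > widths[2]

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0, 0)


class TestConfusionMetrics:
    def test_model_a_column(self):
        rep = confusion_metrics(CM_A)
        points = {name: rep.metrics[name].point_percent for name in rep.metrics}
        assert points == {
            "accuracy": 64, "sensitivity": 77, "specificity": 50, "ppv": 63, "npv": 66,
        }
        assert (rep.metrics["accuracy"].ci_low_percent,
                rep.metrics["accuracy"].ci_high_percent) == (42.0, 87.4)
        assert (rep.metrics["ppv"].ci_low_percent,
                rep.metrics["ppv"].ci_high_percent) == (35.2, 92.1)
        assert (rep.metrics["npv"].ci_low_percent,
                rep.metrics["npv"].ci_high_percent) == (28.9, 100.0)

    def test_model_b_column(self):
        rep = confusion_metrics(CM_B)
        points = {name: rep.metrics[name].point_percent for name in rep.metrics}
        assert points == {
            "accuracy": 58, "sensitivity": 66, "specificity": 50, "ppv": 60, "npv": 57,
        }
        assert (rep.metrics["accuracy"].ci_low_percent,
                rep.metrics["accuracy"].ci_high_percent) == (35.4, 82.2)
        assert (rep.metrics["ppv"].ci_low_percent,
                rep.metrics["ppv"].ci_high_percent) == (29.6, 90.4)
        assert (rep.metrics["npv"].ci_low_percent,
                rep.metrics["npv"].ci_high_percent) == (20.5, 93.8)

    def test_perfect_matrix_all_100_capped(self):
        rep = confusion_metrics(ConfusionMatrix(tp=1, fn=0, fp=0, tn=1))
        for v in rep.metrics.values():
            assert v.point_percent == 100
            assert v.ci_high_percent == 100.0

    def test_transposed_labels_swap_metric_pairs(self, rng):
        for cm in random_tables(20, rng):
            swapped = ConfusionMatrix(tp=cm.tn, fn=cm.fp, fp=cm.fn, tn=cm.tp)
            a, b = confusion_metrics(cm).metrics, confusion_metrics(swapped).metrics
            for x, y in (("sensitivity", "specificity"), ("ppv", "npv")):
                if a[x] is not None:
                    assert a[x].point_percent == b[y].point_percent
                if a[y] is not None:
                    assert a[y].point_percent == b[x].point_percent

    def test_undefined_denominator_reported_as_none(self):
        rep = confusion_metrics(ConfusionMatrix(tp=0, fn=0, fp=2, tn=3))
        assert rep.metrics["sensitivity"] is None
        assert rep.metrics["specificity"] is not None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, fn=0, fp=0, tn=0)


class TestChiSquareFamily:
    def test_balanced_table_is_null(self):
        cm = ConfusionMatrix(5, 5, 5, 5)
        assert pearson_chi2(cm) == (0.0, 1.0)
        assert yates_chi2(cm) == (0.0, 1.0)

    def test_diagonal_table_hand_computation(self):
        cm = ConfusionMatrix(10, 0, 0, 10)
        stat, p = pearson_chi2(cm)
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(float(chi2.sf(20.0, 1)))
        mh_stat, _ = mantel_haenszel_chi2(cm)
        assert mh_stat == pytest.approx(19.0)

    def test_pearson_matches_direct_formula_on_random_tables(self, rng):
        for cm in random_tables(50, rng):
            O = cm.table
            r, c, n = O.sum(1), O.sum(0), O.sum()
            if (r == 0).any() or (c == 0).any():
                assert pearson_chi2(cm) == (0.0, 1.0)
                continue
            E = np.outer(r, c) / n
            expected = float(((O - E) ** 2 / E).sum())
            assert pearson_chi2(cm)[0] == pytest.approx(expected, rel=1e-12)

    def test_yates_dominated_by_pearson(self, rng):
        for cm in random_tables(50, rng):
            assert yates_chi2(cm)[0] <= pearson_chi2(cm)[0] + 1e-12
            assert yates_chi2(cm)[1] >= pearson_chi2(cm)[1] - 1e-12

    def test_yates_correction_floors_at_zero(self):
        # all |O - E| <= 0.5: statistic must be exactly 0
        cm = ConfusionMatrix(2, 2, 2, 3)
        assert abs(cm.table - np.outer(cm.table.sum(1), cm.table.sum(0)) / cm.n).max() <= 0.5
        assert yates_chi2(cm)[0] == 0.0

    def test_mantel_haenszel_defining_relation(self, rng):
        for cm in random_tables(50, rng):
            if cm.n <= 1:
                continue
            expected = (cm.n - 1) / cm.n * pearson_chi2(cm)[0]
            stat, p = mantel_haenszel_chi2(cm)
            assert stat == pytest.approx(expected, rel=1e-12)
            assert p >= pearson_chi2(cm)[1] - 1e-12

    def test_mantel_haenszel_needs_n_above_one(self):
        with pytest.raises(ValueError):
            mantel_haenszel_chi2(ConfusionMatrix(1, 0, 0, 0))

    def test_pvalues_in_unit_interval(self, rng):
        for cm in random_tables(30, rng):
            for fn in (pearson_chi2, yates_chi2):
                assert 0.0 <= fn(cm)[1] <= 1.0
            assert 0.0 <= fisher_exact(cm) <= 1.0


def fisher_enumeration(cm):
    """Exhaustive hypergeometric oracle for the two-sided Fisher p."""
    a, b, c, d = cm.tp, cm.fn, cm.fp, cm.tn
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    def test_exhaustive_sweep_small_tables(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        cm = ConfusionMatrix(a, b, c, d)
                        assert fisher_exact(cm) == pytest.approx(
                            fisher_enumeration(cm), rel=1e-9, abs=1e-12
                        )

    def test_frozen_small_table(self):
        assert fisher_exact(ConfusionMatrix(3, 2, 3, 3)) == pytest.approx(
            fisher_enumeration(ConfusionMatrix(3, 2, 3, 3))
        )

    def test_perfect_diagonal(self):
        # only the two extreme tables are as unlikely as the observed one
        expected = 2.0 / math.comb(10, 5)
        assert fisher_exact(ConfusionMatrix(5, 0, 0, 5)) == pytest.approx(expected)

    def test_zero_margin_gives_one(self):
        assert fisher_exact(ConfusionMatrix(0, 0, 3, 4)) == 1.0


class TestTTestFromSummary:
    def test_cohort_age_comparison_rounds_to_001(self):
        # 8.16 +/- 3.48 (n=6) vs 14 +/- 2.23 (n=5), pooled Student t
        t, df, p = t_test_from_summary(8.16, 3.48, 6, 14.0, 2.23, 5)
        assert df == 9
        assert round(p, 2) == 0.01

    def test_identical_summaries_null(self):
        t, df, p = t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_degenerate_zero_sd_convention(self):
        t, df, p = t_test_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5)
        assert (t, p) == (0.0, 1.0)

    def test_agrees_with_raw_data_t_test(self, rng):
        from scipy.stats import ttest_ind

        x = rng.standard_normal(1000) * 2.0 + 1.0
        y = rng.standard_normal(800) * 1.5 - 0.2
        for variant, equal_var in (("pooled", True), ("welch", False)):
            t_raw = ttest_ind(x, y, equal_var=equal_var)
            t_sum, _, p_sum = t_test_from_summary(
                x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y),
                variant=variant,
            )
            assert t_sum == pytest.approx(t_raw.statistic, rel=1e-10)
            assert p_sum == pytest.approx(t_raw.pvalue, rel=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test_from_summary(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestExternalValidate:
    def test_perfectly_separated_cohort_scores_100(self):
        # train/validate split of one widely separated cohort (9 vs 8 held out)
        cfg = SimulationConfig(n_asthma=29, n_control=28, delta=40.0,
                               sigma_subject=0.0, seed=51)
        prints, _ = simulate_breathprints(cfg)
        train = prints.subset(list(range(0, 20)) + list(range(29, 49)))
        val = prints.subset(list(range(20, 29)) + list(range(49, 57)))
        rep = external_validate(fit_model(train), val)
        for v in rep.metrics.values():
            assert v.point_percent == 100
        assert set(rep.association_pvalues) == {
            "pearson_chi2", "yates", "mantel_haenszel", "fisher_exact",
        }

    def test_null_model_near_chance(self):
        prints, _ = simulate_breathprints(
            SimulationConfig(n_asthma=300, n_control=300, delta=0.0, seed=55)
        )
        train = prints.subset(list(range(0, 50)) + list(range(300, 350)))
        val = prints.subset(list(range(50, 300)) + list(range(350, 600)))
        rep = external_validate(fit_model(train), val)
        assert abs(rep.metrics["accuracy"].point_percent - 50) <= 10

    def test_unlabelled_print_rejected(self, small_cohort):
        import dataclasses

        prints, _ = small_cohort
        model = fit_model(prints)
        from breathprint import BreathPrintSet

        bad = BreathPrintSet([dataclasses.replace(prints[0], group="unknown")])
        with pytest.raises(ValueError, match="unlabelled"):
            external_validate(model, bad)
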
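"""Accuracy metrics, binomial intervals and 2x2 chi-square tests."""

import warnings
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from luscore.diagnostics import (
    SmallExpectedCountWarning,
    TwoByTwo,
    UndefinedMetricError,
    accuracy_panel,
    clopper_pearson_interval,
    npv,
    pearson_chi2_2x2,
    ppv,
    sensitivity,
    specificity,
    two_by_two_from_cohort,
    two_by_two_from_groups,
    wilson_interval,
)

# Reconstructed oxygen-need table of the source study: the unique
# non-negative integer 2x2 with n=106, 29 condition-positives, and the
# printed sensitivity 96.6 % / specificity 98.7 %.
STUDY_TABLE = TwoByTwo(tp=28, fp=1, fn=1, tn=76)


def record(total, oxygen):
    return SimpleNamespace(lus_total=total, oxygen_required=oxygen)


class TestTwoByTwoFromCohort:
    def test_single_true_positive(self):
        t = two_by_two_from_cohort([record(5, True)])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 0)

    def test_mixed_pair(self):
        t = two_by_two_from_cohort([record(5, True), record(1, False)])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            two_by_two_from_cohort([])

    def test_matches_brute_force_record_counting(self):
        rng = np.random.default_rng(11)
        records = [
            record(int(rng.integers(0, 9)), bool(rng.random() < 0.3))
            for _ in range(200)
        ]
        t = two_by_two_from_cohort(records)
        tp = sum(1 for r in records if r.lus_total > 3 and r.oxygen_required)
        fn = sum(1 for r in records if r.lus_total <= 3 and r.oxygen_required)
        tn = sum(1 for r in records if r.lus_total <= 3 and not r.oxygen_required)
        assert (t.tp, t.fn, t.tn) == (tp, fn, tn)
        assert sensitivity(t).point == pytest.approx(tp / (tp + fn))
        assert npv(t).point == pytest.approx(tn / (tn + fn))


class TestAccuracyMetrics:
    def test_study_table_reproduces_printed_metrics(self):
        panel = accuracy_panel(STUDY_TABLE)
        assert panel["sensitivity"].point == pytest.approx(0.9655, abs=5e-5)
        assert panel["specificity"].point == pytest.approx(0.9870, abs=5e-5)
        assert panel["ppv"].point == pytest.approx(0.9655, abs=5e-5)
        assert panel["npv"].point == pytest.approx(0.9870, abs=5e-5)

    def test_perfect_classifier(self):
        t = TwoByTwo(tp=10, fp=0, fn=0, tn=10)
        assert all(e.point == 1.0 for e in accuracy_panel(t).values())

    def test_ppv_undefined_without_positive_predictions(self):
        t = TwoByTwo(tp=0, fp=0, fn=10, tn=10)
        assert sensitivity(t).point == 0.0
        assert npv(t).point == 0.5
        with pytest.raises(UndefinedMetricError, match="ppv"):
            ppv(t)

    def test_negative_or_empty_table_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(tp=-1, fp=0, fn=0, tn=5)
        with pytest.raises(ValueError):
            TwoByTwo(tp=0, fp=0, fn=0, tn=0)


class TestWilson:
    def test_printed_specificity_interval(self):
        low, high = wilson_interval(76, 77)
        assert low == pytest.approx(0.930, abs=5e-4)
        assert high == pytest.approx(0.998, abs=5e-4)

    def test_closed_form_at_half(self):
        low, high = wilson_interval(50, 100)
        assert low == pytest.approx(0.404, abs=5e-4)
        assert high == pytest.approx(0.596, abs=5e-4)

    def test_boundary_all_successes(self):
        low, high = wilson_interval(20, 20)
        assert low < 1.0
        assert high <= 1.0
        assert low <= 1.0 <= high or low <= 20 / 20 <= high

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(5, 0)
        with pytest.raises(ValueError):
            wilson_interval(-1, 10)
        with pytest.raises(ValueError):
            wilson_interval(11, 10)


class TestClopperPearson:
    def test_all_successes_closed_form(self):
        low, high = clopper_pearson_interval(29, 29)
        assert low == pytest.approx(0.025 ** (1 / 29), abs=1e-9)
        assert high == 1.0

    def test_printed_sensitivity_lower_bound(self):
        low, _ = clopper_pearson_interval(28, 29)
        assert low == pytest.approx(0.822, abs=5e-4)

    def test_zero_successes(self):
        low, _ = clopper_pearson_interval(0, 10)
        assert low == 0.0

    @pytest.mark.parametrize("x,n", [(0, 15), (3, 7), (10, 10), (76, 77)])
    def test_matches_statsmodels(self, x, n):
        from statsmodels.stats.proportion import proportion_confint

        ours = clopper_pearson_interval(x, n)
        ref = proportion_confint(x, n, alpha=0.05, method="beta")
        assert ours == pytest.approx(ref, abs=1e-10)
        ours_w = wilson_interval(x, n)
        ref_w = proportion_confint(x, n, alpha=0.05, method="wilson")
        assert ours_w == pytest.approx(ref_w, abs=1e-10)


def shortcut_chi2(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestChiSquare:
    def test_printed_severity_extension_row(self):
        res = pearson_chi2_2x2([[61, 15], [3, 27]])
        assert res.statistic == pytest.approx(44.39, abs=5e-3)
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        res = pearson_chi2_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_printed_srv_anterolateral_row(self):
        res = pearson_chi2_2x2([[27, 6], [37, 36]])
        assert res.statistic == pytest.approx(9.21, abs=5e-3)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pearson_chi2_2x2([[0, 0], [5, 5]])

    def test_small_expected_count_warns_but_computes(self):
        with pytest.warns(SmallExpectedCountWarning):
            res = pearson_chi2_2x2([[1, 5], [4, 1]])
        assert res.statistic > 0

    def test_expected_counts_stored(self):
        res = pearson_chi2_2x2([[20, 30], [30, 20]])
        assert res.expected_counts == pytest.approx(np.full((2, 2), 25.0))


class TestTwoByTwoFromGroups:
    @pytest.mark.parametrize(
        "args,expected",
        [((61, 76, 3, 30), [[61, 15], [3, 27]]),
         ((0, 5, 5, 5), [[0, 5], [5, 0]]),
         ((4, 77, 12, 29), [[4, 73], [12, 17]])],
    )
    def test_group_rows(self, args, expected):
        assert (two_by_two_from_groups(*args) == np.array(expected)).all()

    def test_pos_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            two_by_two_from_groups(6, 5, 0, 5)


@st.composite
def contingency_tables(draw):
    cells = [draw(st.integers(0, 50)) for _ in range(4)]
    table = np.array(cells).reshape(2, 2)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        table += 1
    return table


@settings(deadline=None, max_examples=80)
@given(table=contingency_tables())
def test_chi2_shortcut_equals_expected_count_oracle(table):
    """n(ad-bc)^2/(marginal product) == sum (obs-exp)^2/exp from independence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallExpectedCountWarning)
        res = pearson_chi2_2x2(table)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    oracle = float(((table - expected) ** 2 / expected).sum())
    assert res.statistic == pytest.approx(oracle, abs=1e-9)
    assert res.statistic == pytest.approx(shortcut_chi2(table), abs=1e-9)


@settings(deadline=None, max_examples=80)
@given(table=contingency_tables())
def test_chi2_invariant_under_row_and_column_swap(table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallExpectedCountWarning)
        base = pearson_chi2_2x2(table).statistic
        rows = pearson_chi2_2x2(table[::-1]).statistic
        cols = pearson_chi2_2x2(table[:, ::-1]).statistic
    assert rows == pytest.approx(base, abs=1e-9)
    assert cols == pytest.approx(base, abs=1e-9)


@settings(deadline=None, max_examples=80)
@given(n=st.integers(1, 200), frac=st.floats(0, 1))
def test_intervals_contain_point_and_exact_is_wider(n, frac):
    x = round(n * frac)
    w_low, w_high = wilson_interval(x, n)
    c_low, c_high = clopper_pearson_interval(x, n)
    p = x / n
    assert w_low <= p <= w_high
    assert c_low <= p <= c_high
    if 0 < x < n:
        assert (c_high - c_low) >= (w_high - w_low) - 1e-12
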
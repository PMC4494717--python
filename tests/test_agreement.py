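"""Cohen's kappa machinery, checked against closed forms and statsmodels."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from luscore.agreement import (
    ConfusionMatrix,
    DegenerateMarginalsError,
    cohen_kappa,
    confusion_from_pairs,
    expected_agreement,
    kappa_analysis,
    kappa_se0,
    kappa_z_test,
    observed_agreement,
)

GRADES = ("normal", "mild", "moderate", "severe")

# Published rater-pair marginals: attending clinician vs pediatric
# sonographer, then pediatric vs radiologist sonographer (n = 106), in
# category order mild, moderate, severe, normal.
PAIR1 = dict(rows=(76, 27, 3, 0), cols=(68, 26, 3, 9), n=106, diag=96)
PAIR2 = dict(rows=(68, 26, 3, 9), cols=(65, 26, 3, 12), n=106, diag=95)


class TestConfusionMatrix:
    def test_all_ordered_combinations_fill_every_cell(self):
        pairs = list(itertools.product(GRADES, GRADES))
        cm = confusion_from_pairs(pairs, GRADES)
        assert cm.n == 16
        assert (cm.counts == 1).all()

    def test_identical_pairs_are_diagonal(self):
        cm = confusion_from_pairs([("mild", "mild")] * 106, GRADES)
        assert cm.n == 106
        assert np.trace(cm.counts) == 106

    def test_unknown_category_and_empty_input_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            confusion_from_pairs([("mild", "critical")], GRADES)
        with pytest.raises(ValueError, match="empty"):
            confusion_from_pairs([], GRADES)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(counts=np.array([[1, -1], [0, 2]]), categories=("a", "b"))


class TestObservedAgreement:
    def test_diagonal_matrix_gives_one(self):
        cm = ConfusionMatrix(counts=np.diag([5, 3, 2, 1]), categories=GRADES)
        assert observed_agreement(cm) == 1.0

    def test_uniform_matrix(self):
        cm = ConfusionMatrix(counts=np.ones((4, 4), dtype=int), categories=GRADES)
        assert observed_agreement(cm) == 0.25

    def test_study_diagonal(self):
        assert PAIR1["diag"] / PAIR1["n"] == pytest.approx(0.9057, abs=5e-5)


class TestExpectedAgreement:
    def test_published_marginals(self):
        pe1 = expected_agreement(PAIR1["rows"], PAIR1["cols"], 106)
        pe2 = expected_agreement(PAIR2["rows"], PAIR2["cols"], 106)
        assert pe1 == pytest.approx(0.5232, abs=5e-5)
        assert pe2 == pytest.approx(0.4640, abs=5e-5)

    def test_single_category_degenerate(self):
        assert expected_agreement((10, 0, 0), (10, 0, 0), 10) == 1.0

    def test_marginal_sum_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum to n"):
            expected_agreement((5, 5), (5, 4), 10)


class TestKappa:
    def test_published_value(self):
        assert cohen_kappa(0.9057, 0.5232) == pytest.approx(0.802, abs=5e-4)

    def test_chance_level_is_zero_and_perfect_is_one(self):
        assert cohen_kappa(0.3, 0.3) == 0.0
        assert cohen_kappa(1.0, 0.7) == 1.0

    def test_degenerate_pe_raises(self):
        with pytest.raises(DegenerateMarginalsError):
            cohen_kappa(1.0, 1.0)


class TestKappaSE0:
    def test_published_standard_errors(self):
        assert kappa_se0(PAIR1["rows"], PAIR1["cols"], 106) == pytest.approx(
            0.0765, abs=5e-5
        )
        assert kappa_se0(PAIR2["rows"], PAIR2["cols"], 106) == pytest.approx(
            0.0711, abs=5e-5
        )

    def test_symmetric_binary_closed_form(self):
        # Pe = 0.5, sum p q (p+q) = 0.5 -> sqrt(0.25) / (0.5 * 10) = 0.1
        assert kappa_se0((50, 50), (50, 50), 100) == pytest.approx(0.1)

    def test_scales_as_inverse_sqrt_n(self):
        base = kappa_se0((60, 30, 10), (50, 30, 20), 100)
        scaled = kappa_se0((240, 120, 40), (200, 120, 80), 400)
        assert scaled == pytest.approx(base / 2)


class TestZTest:
    def test_published_z(self):
        z, p = kappa_z_test(0.80642, 0.071145)
        assert z == pytest.approx(11.33, abs=5e-3)
        assert p < 1e-6

    def test_null_kappa(self):
        z, p = kappa_z_test(0.0, 0.1)
        assert (z, p) == (0.0, 0.5)

    def test_normal_quantile(self):
        _, p = kappa_z_test(0.196, 0.1)
        assert p == pytest.approx(0.025, abs=5e-4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            kappa_z_test(0.5, 0.0)


@st.composite
def small_tables(draw, k=3, max_n=30):
    cells = draw(
        st.lists(st.integers(0, max_n // 2), min_size=k * k, max_size=k * k)
    )
    table = np.array(cells).reshape(k, k)
    # both raters must use at least two categories
    if (table.sum(axis=0) > 0).sum() < 2 or (table.sum(axis=1) > 0).sum() < 2:
        table[0, 1] += 1
        table[1, 0] += 1
    return table


@settings(deadline=None, max_examples=60)
@given(table=small_tables())
def test_expected_agreement_equals_independence_table_trace(table):
    """Pe from the marginals equals Po of the outer-product independence table."""
    cm = ConfusionMatrix(counts=table, categories=("a", "b", "c"))
    pe = expected_agreement(cm.row_marginals, cm.col_marginals, cm.n)
    independent = np.outer(cm.row_marginals, cm.col_marginals) / cm.n
    assert pe == pytest.approx(float(np.trace(independent)) / cm.n)


@settings(deadline=None, max_examples=60)
@given(table=small_tables())
def test_kappa_matches_sklearn_oracle(table):
    """Formula kappa equals scikit-learn's pair-level computation."""
    from sklearn.metrics import cohen_kappa_score

    labels_a, labels_b = [], []
    for i, j in itertools.product(range(3), repeat=2):
        labels_a += [i] * int(table[i, j])
        labels_b += [j] * int(table[i, j])
    cm = ConfusionMatrix(counts=table, categories=(0, 1, 2))
    res = kappa_analysis(cm)
    oracle = cohen_kappa_score(labels_a, labels_b, labels=[0, 1, 2])
    assert res.kappa == pytest.approx(oracle, abs=1e-12)


def test_full_analysis_cross_checked_against_statsmodels():
    """kappa and the H0 standard error agree with statsmodels on a full table."""
    from statsmodels.stats.inter_rater import cohens_kappa

    rng = np.random.default_rng(7)
    table = rng.integers(0, 15, size=(4, 4))
    table[np.diag_indices(4)] += 20  # realistic: raters mostly agree
    cm = ConfusionMatrix(counts=table, categories=GRADES)
    ours = kappa_analysis(cm)
    ref = cohens_kappa(table, return_results=True)
    assert ours.kappa == pytest.approx(ref.kappa, abs=1e-12)
    assert ours.se0 == pytest.approx(ref.std_kappa0, abs=1e-12)
    assert ours.z == pytest.approx(ref.z_value, rel=1e-10)


@given(
    counts=st.lists(st.integers(1, 20), min_size=2, max_size=4),
)
def test_perfect_agreement_has_kappa_one(counts):
    cats = GRADES[: len(counts)]
    pairs = [(c, c) for c, k in zip(cats, counts) for _ in range(k)]
    if len(set(c for c, _ in pairs)) < 2:
        return  # single category -> Pe = 1, kappa undefined
    res = kappa_analysis(confusion_from_pairs(pairs, cats))
    assert res.po == 1.0
    assert res.kappa == pytest.approx(1.0)
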
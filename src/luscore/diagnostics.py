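"""Diagnostic accuracy of the oxygen-need rule and 2x2 group comparisons.

The oxygen-need classifier (LUS total > 3) is evaluated against the
observed oxygen requirement as a 2x2 table, from which sensitivity,
specificity and predictive values are estimated with binomial confidence
intervals (Wilson score by default; exact Clopper-Pearson optionally).

Group comparisons of finding frequencies (e.g. mild vs moderate-severe
disease, oxygen vs no oxygen, RSV-positive vs RSV-negative) use Pearson's
chi-square on the 2x2 contingency table without continuity correction.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scoring import ScoringConfig, DEFAULT_CONFIG, predict_oxygen_need

__all__ = [
    "TwoByTwo",
    "ProportionEstimate",
    "ChiSquareResult",
    "UndefinedMetricError",
    "SmallExpectedCountWarning",
    "two_by_two_from_cohort",
    "two_by_two_from_groups",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "accuracy_panel",
    "wilson_interval",
    "clopper_pearson_interval",
    "pearson_chi2_2x2",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (e.g. PPV with no positive predictions)."""


class SmallExpectedCountWarning(UserWarning):
    """An expected cell count below 5: the chi-square approximation is rough."""


@dataclass(frozen=True)
class TwoByTwo:
    """Classifier-vs-condition cell counts: TP, FP, FN, TN."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def n(self) -> int:
        return int(self.tp + self.fp + self.fn + self.tn)

    @property
    def condition_positives(self) -> int:
        return int(self.tp + self.fn)

    @property
    def condition_negatives(self) -> int:
        return int(self.fp + self.tn)

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its confidence interval."""

    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    method: str
    confidence: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("interval must contain the point estimate")


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square on a 2x2 table (df = 1, no continuity correction)."""

    statistic: float
    df: int
    p_value: float
    expected_counts: np.ndarray


def two_by_two_from_cohort(
    records: Iterable, config: ScoringConfig = DEFAULT_CONFIG
) -> TwoByTwo:
    """Tabulate the oxygen-need rule against the observed oxygen outcome.

    Each record needs a ``lus_total`` (int, 0-8) and an ``oxygen_required``
    boolean; the test is ``predict_oxygen_need(lus_total)``.
    """
    tp = fp = fn = tn = 0
    count = 0
    for rec in records:
        count += 1
        predicted = predict_oxygen_need(rec.lus_total, config)
        actual = bool(rec.oxygen_required)
        if predicted and actual:
            tp += 1
        elif predicted and not actual:
            fp += 1
        elif not predicted and actual:
            fn += 1
        else:
            tn += 1
    if count == 0:
        raise ValueError("cannot tabulate an empty cohort")
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def two_by_two_from_groups(
    pos_a: int, n_a: int, pos_b: int, n_b: int
) -> np.ndarray:
    """Build the 2x2 contingency table for a finding counted in two groups.

    Rows are groups A and B; columns are with-finding / without-finding.
    """
    for pos, n, grp in ((pos_a, n_a, "A"), (pos_b, n_b, "B")):
        if not 0 <= pos <= n:
            raise ValueError(f"group {grp}: need 0 <= pos <= n, got {pos}/{n}")
    return np.array([[pos_a, n_a - pos_a], [pos_b, n_b - pos_b]], dtype=np.int64)


def wilson_interval(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    _check_binomial(x, n, confidence)
    z = stats.norm.ppf(0.5 + confidence / 2)
    phat = x / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    # endpoints are exactly 0/1 at x=0/x=n; avoid floating-point shortfall
    low = 0.0 if x == 0 else float(max(0.0, centre - half))
    high = 1.0 if x == n else float(min(1.0, centre + half))
    return low, high


def clopper_pearson_interval(
    x: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) beta-quantile interval for a binomial proportion."""
    _check_binomial(x, n, confidence)
    alpha = 1 - confidence
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


_CI_METHODS = {
    "wilson": wilson_interval,
    "clopper_pearson": clopper_pearson_interval,
}


def _check_binomial(x: int, n: int, confidence: float) -> None:
    if isinstance(n, bool) or not isinstance(n, (int, np.integer)) or n <= 0:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if isinstance(x, bool) or not isinstance(x, (int, np.integer)) or not 0 <= x <= n:
        raise ValueError(f"x must be an integer in 0..{n}, got {x!r}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")


def _proportion(
    x: int, n: int, metric: str, ci_method: str, confidence: float
) -> ProportionEstimate:
    if n == 0:
        raise UndefinedMetricError(f"{metric} is undefined: denominator is zero")
    try:
        interval = _CI_METHODS[ci_method]
    except KeyError:
        raise ValueError(
            f"unknown ci_method {ci_method!r}; choose from {sorted(_CI_METHODS)}"
        ) from None
    low, high = interval(x, n, confidence)
    return ProportionEstimate(
        numerator=int(x),
        denominator=int(n),
        point=x / n,
        ci_low=low,
        ci_high=high,
        method=ci_method,
        confidence=confidence,
    )


def sensitivity(
    t: TwoByTwo, ci_method: str = "wilson", confidence: float = 0.95
) -> ProportionEstimate:
    """TP / (TP + FN): the fraction of oxygen-requiring infants flagged."""
    return _proportion(t.tp, t.tp + t.fn, "sensitivity", ci_method, confidence)


def specificity(
    t: TwoByTwo, ci_method: str = "wilson", confidence: float = 0.95
) -> ProportionEstimate:
    """TN / (TN + FP): the fraction of non-requiring infants cleared."""
    return _proportion(t.tn, t.tn + t.fp, "specificity", ci_method, confidence)


def ppv(
    t: TwoByTwo, ci_method: str = "wilson", confidence: float = 0.95
) -> ProportionEstimate:
    """TP / (TP + FP): positive predictive value."""
    return _proportion(t.tp, t.tp + t.fp, "ppv", ci_method, confidence)


def npv(
    t: TwoByTwo, ci_method: str = "wilson", confidence: float = 0.95
) -> ProportionEstimate:
    """TN / (TN + FN): negative predictive value."""
    return _proportion(t.tn, t.tn + t.fn, "npv", ci_method, confidence)


def accuracy_panel(
    t: TwoByTwo, ci_method: str = "wilson", confidence: float = 0.95
) -> dict[str, ProportionEstimate]:
    """Sensitivity, specificity, PPV and NPV of one 2x2 table."""
    return {
        "sensitivity": sensitivity(t, ci_method, confidence),
        "specificity": specificity(t, ci_method, confidence),
        "ppv": ppv(t, ci_method, confidence),
        "npv": npv(t, ci_method, confidence),
    }


def pearson_chi2_2x2(table: np.ndarray) -> ChiSquareResult:
    """Pearson chi-square for a 2x2 contingency table, no continuity correction.

    Equivalent to the shortcut n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    Emits :class:`SmallExpectedCountWarning` when any expected cell is
    below 5, but still computes (the approximation degrades, it does not
    break).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("every row and column sum must be positive")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn(
            "expected cell count below 5; chi-square approximation is rough",
            SmallExpectedCountWarning,
            stacklevel=2,
        )
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected_counts=res.expected_freq,
    )
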
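"""Inter-rater agreement: cross-tabulation, Cohen's kappa and its null-hypothesis z-test.

Agreement between two raters assigning the same ordered severity
categories is summarised by the observed agreement proportion
``Po = trace / n``, the chance-expected agreement
``Pe = sum_i p_i. * p_.i`` computed from the marginal proportions, and
Cohen's kappa ``K = (Po - Pe) / (1 - Pe)``.

Significance is assessed with the large-sample test of H0: kappa = 0,
whose standard error depends only on the marginals::

    se0 = sqrt(Pe + Pe^2 - sum_i p_i. * p_.i * (p_i. + p_.i)) / ((1 - Pe) * sqrt(n))

and ``z = K / se0`` referred to the upper tail of the standard normal.
Kappa here is unweighted; the severity grades are ordinal but no
disagreement weighting is applied.
"""

from __future__ import annotations

from collections.abc import Hashable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "KappaResult",
    "confusion_from_pairs",
    "observed_agreement",
    "expected_agreement",
    "cohen_kappa",
    "kappa_se0",
    "kappa_z_test",
    "kappa_analysis",
]


class DegenerateMarginalsError(ValueError):
    """Raised when both raters use a single category (Pe = 1, kappa undefined)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k cross-tabulation of two raters' categories.

    Rows are rater A, columns rater B, in the shared ``categories`` order.
    """

    counts: np.ndarray
    categories: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.categories)
        if counts.shape != (k, k):
            raise ValueError(
                f"counts must be {k}x{k} to match categories, got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("confusion matrix must contain at least one pair")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class KappaResult:
    """Agreement summary for one rater pair."""

    po: float
    pe: float
    kappa: float
    se0: float
    z: float
    p_value: float

    def display_p(self) -> str:
        """p truncated to three decimals, the study's reporting convention."""
        return f"{int(self.p_value * 1000) / 1000:.3f}"


def confusion_from_pairs(
    pairs: Sequence[tuple[Hashable, Hashable]],
    categories: Sequence[Hashable],
) -> ConfusionMatrix:
    """Tabulate (rater A, rater B) category pairs into a confusion matrix."""
    if len(pairs) == 0:
        raise ValueError("cannot tabulate an empty pair sequence")
    categories = tuple(categories)
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for a, b in pairs:
        if a not in index:
            raise ValueError(f"unknown category for rater A: {a!r}")
        if b not in index:
            raise ValueError(f"unknown category for rater B: {b!r}")
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts=counts, categories=categories)


def observed_agreement(cm: ConfusionMatrix) -> float:
    """Proportion of pairs on the diagonal: trace / n."""
    return float(np.trace(cm.counts)) / cm.n


def expected_agreement(
    row_marginals: Sequence[int], col_marginals: Sequence[int], n: int
) -> float:
    """Chance agreement under marginal independence: sum_i (r_i/n)(c_i/n)."""
    r = np.asarray(row_marginals, dtype=float)
    c = np.asarray(col_marginals, dtype=float)
    if r.shape != c.shape:
        raise ValueError("marginal vectors must have the same length")
    if n <= 0:
        raise ValueError("n must be positive")
    if r.sum() != n or c.sum() != n:
        raise ValueError(
            f"marginals must each sum to n={n} (got {r.sum():g} and {c.sum():g})"
        )
    return float((r / n) @ (c / n))


def cohen_kappa(po: float, pe: float) -> float:
    """Chance-corrected agreement (Po - Pe) / (1 - Pe)."""
    if not 0 <= po <= 1:
        raise ValueError(f"po must be in [0, 1], got {po}")
    if not 0 <= pe <= 1:
        raise ValueError(f"pe must be in [0, 1], got {pe}")
    if pe == 1:
        raise DegenerateMarginalsError(
            "expected agreement is 1 (single shared category); kappa undefined"
        )
    return (po - pe) / (1 - pe)


def kappa_se0(
    row_marginals: Sequence[int], col_marginals: Sequence[int], n: int
) -> float:
    """Standard error of kappa under H0 (kappa = 0), from the marginals alone."""
    pe = expected_agreement(row_marginals, col_marginals, n)
    if pe == 1:
        raise DegenerateMarginalsError(
            "expected agreement is 1 (single shared category); se0 undefined"
        )
    p = np.asarray(row_marginals, dtype=float) / n
    q = np.asarray(col_marginals, dtype=float) / n
    s = float(np.sum(p * q * (p + q)))
    return float(np.sqrt(pe + pe**2 - s) / ((1 - pe) * np.sqrt(n)))


def kappa_z_test(kappa: float, se0: float) -> tuple[float, float]:
    """z = kappa / se0 with its one-sided upper-tail normal p-value."""
    if se0 <= 0:
        raise ValueError(f"se0 must be positive, got {se0}")
    z = kappa / se0
    p = float(stats.norm.sf(z))
    return z, p


def kappa_analysis(cm: ConfusionMatrix) -> KappaResult:
    """Full agreement analysis of one confusion matrix.

    Perfect agreement on a single shared category (Po = Pe = 1) is
    reported as kappa = 1 with no test statistic (se0, z, p are NaN);
    Po < 1 with Pe = 1 stays undefined and raises.
    """
    po = observed_agreement(cm)
    pe = expected_agreement(cm.row_marginals, cm.col_marginals, cm.n)
    if pe == 1 and po == 1:
        nan = float("nan")
        return KappaResult(po=1.0, pe=1.0, kappa=1.0, se0=nan, z=nan, p_value=nan)
    kappa = cohen_kappa(po, pe)
    se0 = kappa_se0(cm.row_marginals, cm.col_marginals, cm.n)
    z, p = kappa_z_test(kappa, se0)
    return KappaResult(po=po, pe=pe, kappa=kappa, se0=se0, z=z, p_value=p)
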
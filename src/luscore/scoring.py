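"""Ordinal severity scoring for infant bronchiolitis.

Two companion rubrics are implemented:

* a **clinical score** — four bedside items (respiratory rate, dyspnea,
  accessory-muscle use, auscultation), each coded 0-3, total 0-12;
* a **lung-ultrasound (LUS) score** — four sonographic components
  (anterolateral pattern, posterior interstitial syndrome, its extension
  over bilaterally involved intercostal spaces, and the largest posterior
  subpleural consolidation), each coded 0-2, total 0-8.

Totals are banded into four severity grades (healthy/normal, mild,
moderate, severe), and the LUS total drives a binary oxygen-need
classifier (total > 3 predicts supplementary-oxygen requirement).

Dyspnea, accessory-muscle and auscultation items are multi-sign clinical
judgments and are accepted only as pre-coded 0-3 values; mechanical
encoders exist only for the numeric inputs (respiratory rate, intercostal
space count, consolidation size).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "SeverityGrade",
    "ClinicalAssessment",
    "LUSExam",
    "ScoreResult",
    "ScoringConfig",
    "encode_respiratory_rate",
    "encode_extension",
    "encode_consolidation",
    "score_clinical",
    "score_lus",
    "grade_clinical",
    "grade_lus",
    "predict_oxygen_need",
]


class SeverityGrade(enum.IntEnum):
    """Four-level severity grade shared by both scales.

    The ordinal code is the enum value: 0 healthy (clinical scale) /
    normal ultrasound pattern (LUS scale), then mild, moderate, severe.
    """

    HEALTHY_OR_NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()


#: Ordered category labels used when cross-tabulating two raters' grades.
GRADE_CATEGORIES: tuple[SeverityGrade, ...] = tuple(SeverityGrade)


def _check_item(name: str, value: int, hi: int) -> None:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValueError(f"{name} must be an integer, got {value!r}")
    if not 0 <= value <= hi:
        raise ValueError(f"{name} must be in 0..{hi}, got {value}")


@dataclass(frozen=True)
class ClinicalAssessment:
    """The four ordinal clinical items for one infant, each 0-3."""

    respiratory_rate_item: int
    dyspnea_item: int
    accessory_muscle_item: int
    auscultation_item: int

    def __post_init__(self) -> None:
        for name in (
            "respiratory_rate_item",
            "dyspnea_item",
            "accessory_muscle_item",
            "auscultation_item",
        ):
            _check_item(name, getattr(self, name), 3)

    @property
    def items(self) -> tuple[int, int, int, int]:
        return (
            self.respiratory_rate_item,
            self.dyspnea_item,
            self.accessory_muscle_item,
            self.auscultation_item,
        )

    @property
    def total(self) -> int:
        return sum(self.items)


@dataclass(frozen=True)
class LUSExam:
    """The four ordinal lung-ultrasound components for one infant/rater, each 0-2."""

    anterolateral_item: int
    posterior_interstitial_item: int
    extension_item: int
    consolidation_item: int

    def __post_init__(self) -> None:
        for name in (
            "anterolateral_item",
            "posterior_interstitial_item",
            "extension_item",
            "consolidation_item",
        ):
            _check_item(name, getattr(self, name), 2)

    @property
    def items(self) -> tuple[int, int, int, int]:
        return (
            self.anterolateral_item,
            self.posterior_interstitial_item,
            self.extension_item,
            self.consolidation_item,
        )

    @property
    def total(self) -> int:
        return sum(self.items)


@dataclass(frozen=True)
class ScoreResult:
    """A score total with its severity grade on one of the two scales."""

    total: int
    grade: SeverityGrade
    scale: str  # "clinical" or "lus"

    def __post_init__(self) -> None:
        if self.scale not in ("clinical", "lus"):
            raise ValueError(f"scale must be 'clinical' or 'lus', got {self.scale!r}")
        hi = 12 if self.scale == "clinical" else 8
        if not 0 <= self.total <= hi:
            raise ValueError(f"{self.scale} total must be in 0..{hi}, got {self.total}")


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable banding rules where the published rubric leaves a gap.

    rr_boundary_70
        Item awarded to a respiratory rate of exactly 70 breaths/min; the
        rubric's bands "61-69" and ">70" leave 70 unassigned. Default 3
        (severity rounds up).
    extension_band_rule
        How the shared endpoints of the "0-6" / "6-12" / ">12" intercostal
        bands are resolved. "lower" (default): 0-6 -> 0, 7-12 -> 1, >=13 -> 2;
        "upper": 0-5 -> 0, 6-12 -> 1, >=13 -> 2.
    oxygen_threshold
        LUS total strictly above this predicts oxygen need. Default 3.
    """

    rr_boundary_70: int = 3
    extension_band_rule: str = "lower"
    oxygen_threshold: int = 3

    def __post_init__(self) -> None:
        if self.rr_boundary_70 not in (2, 3):
            raise ValueError("rr_boundary_70 must be 2 or 3")
        if self.extension_band_rule not in ("lower", "upper"):
            raise ValueError("extension_band_rule must be 'lower' or 'upper'")
        if not 0 <= self.oxygen_threshold <= 8:
            raise ValueError("oxygen_threshold must be in 0..8")


DEFAULT_CONFIG = ScoringConfig()


def encode_respiratory_rate(rr: float, config: ScoringConfig = DEFAULT_CONFIG) -> int:
    """Code a respiratory rate (breaths/min) into the 0-3 clinical item.

    Bands: <50 -> 0, 50-60 -> 1, 61-69 -> 2, >=70 -> 3 (a rate of exactly
    70 goes to the band given by ``config.rr_boundary_70``).
    """
    if not math.isfinite(rr) or rr < 0:
        raise ValueError(f"respiratory rate must be a non-negative number, got {rr!r}")
    if rr < 50:
        return 0
    if rr <= 60:
        return 1
    if rr < 70:
        return 2
    if rr == 70:
        return config.rr_boundary_70
    return 3


def encode_extension(n_spaces: int, config: ScoringConfig = DEFAULT_CONFIG) -> int:
    """Code the count of bilaterally involved posterior intercostal spaces (0-2)."""
    if isinstance(n_spaces, bool) or not isinstance(n_spaces, int):
        raise ValueError(f"space count must be an integer, got {n_spaces!r}")
    if n_spaces < 0:
        raise ValueError(f"space count must be non-negative, got {n_spaces}")
    low_cut = 6 if config.extension_band_rule == "lower" else 5
    if n_spaces <= low_cut:
        return 0
    if n_spaces <= 12:
        return 1
    return 2


def encode_consolidation(max_size_cm: float | None) -> int:
    """Code the largest posterior subpleural consolidation (0-2).

    ``None`` means no consolidation (0); a sub-centimetre lesion codes 1;
    1 cm or more codes 2. A stated size must be positive.
    """
    if max_size_cm is None:
        return 0
    if not math.isfinite(max_size_cm) or max_size_cm <= 0:
        raise ValueError(
            f"a stated consolidation size must be positive, got {max_size_cm!r}"
        )
    return 1 if max_size_cm < 1.0 else 2


def grade_clinical(total: int) -> SeverityGrade:
    """Band a clinical total (0-12): 0 healthy, 1-4 mild, 5-8 moderate, 9-12 severe."""
    if isinstance(total, bool) or not isinstance(total, int) or not 0 <= total <= 12:
        raise ValueError(f"clinical total must be an integer in 0..12, got {total!r}")
    if total == 0:
        return SeverityGrade.HEALTHY_OR_NORMAL
    if total <= 4:
        return SeverityGrade.MILD
    if total <= 8:
        return SeverityGrade.MODERATE
    return SeverityGrade.SEVERE


def grade_lus(total: int) -> SeverityGrade:
    """Band a LUS total (0-8): 0 normal, 1-3 mild, 4-6 moderate, 7-8 severe."""
    if isinstance(total, bool) or not isinstance(total, int) or not 0 <= total <= 8:
        raise ValueError(f"LUS total must be an integer in 0..8, got {total!r}")
    if total == 0:
        return SeverityGrade.HEALTHY_OR_NORMAL
    if total <= 3:
        return SeverityGrade.MILD
    if total <= 6:
        return SeverityGrade.MODERATE
    return SeverityGrade.SEVERE


def score_clinical(a: ClinicalAssessment) -> ScoreResult:
    """Total the four clinical items and band the result."""
    total = a.total
    return ScoreResult(total=total, grade=grade_clinical(total), scale="clinical")


def score_lus(e: LUSExam) -> ScoreResult:
    """Total the four LUS components and band the result."""
    total = e.total
    return ScoreResult(total=total, grade=grade_lus(total), scale="lus")


def predict_oxygen_need(
    lus_total: int, config: ScoringConfig = DEFAULT_CONFIG
) -> bool:
    """Predict supplementary-oxygen requirement from the LUS total.

    True iff the total is strictly greater than the configured threshold
    (default 3). A total of exactly 3 is classified negative: the positive
    class is defined literally as "score > 3".
    """
    if (
        isinstance(lus_total, bool)
        or not isinstance(lus_total, int)
        or not 0 <= lus_total <= 8
    ):
        raise ValueError(f"LUS total must be an integer in 0..8, got {lus_total!r}")
    return lus_total > config.oxygen_threshold
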
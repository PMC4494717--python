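"""Seeded synthetic cohorts of bronchiolitis infants and healthy controls.

The source study published only marginal counts and 2x2 slices, never
patient-level data. This generator draws cohorts whose marginal and
conditional structure matches those counts, so every analysis stage can
be exercised offline.

Generative model (one infant at a time, single RNG stream):

1. A latent severity grade (mild / moderate / severe) is drawn from
   ``severity_probs``; the attending clinician's grade is the latent one,
   with the four clinical items sampled uniformly from the integer tuples
   whose total falls in that grade's band (clinical raters in the study
   assigned no "healthy" grade among cases).
2. The first sonographer's four LUS components are drawn independently
   from severity-conditional tables (``conditional_lus_tables``); the LUS
   grade follows from the total. Clinical items and LUS findings are thus
   conditionally independent given latent severity — the simplest
   structure that reproduces the published agreement levels.
3. The second sonographer's grade is the first's passed through an
   adjacent-grade confusion kernel (``rater2_stay_prob``); their exam
   items are re-drawn uniformly within the resulting grade band when the
   grade moves.
4. Oxygen requirement is Bernoulli with probability ``oxygen_given_total``
   indexed by the first sonographer's LUS total — a monotone step that
   makes the ">3" rule a strong but imperfect classifier and yields an
   overall prevalence near the study's 27 %.
5. RSV positivity is Bernoulli(``srv_prevalence``) in cases, always
   negative in controls. Demographics (age, sex, delivery mode, feeding,
   prematurity) are generated for realism and used by no analysis stage.

Controls score 0 on both scales; one in five carries an isolated B-line,
which the rubric codes 0 (no pathological significance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .scoring import ClinicalAssessment, LUSExam, grade_lus

__all__ = ["CohortRecord", "CohortParams", "generate_cohort", "DEFAULT_PARAMS"]


@dataclass(frozen=True)
class CohortRecord:
    """One infant: raw item codes per rater plus outcomes."""

    patient_id: str
    age_days: int
    is_control: bool
    clinical_items: ClinicalAssessment
    lus_exam_rater1: LUSExam
    lus_exam_rater2: LUSExam
    oxygen_required: bool
    srv_positive: bool
    sex: str = "f"
    delivery: str = "vaginal"
    breastfed: bool = True
    preterm: bool = False
    isolated_b_line: bool = False
    resolved_at_discharge: bool = True

    @property
    def clinical_total(self) -> int:
        return self.clinical_items.total

    @property
    def lus_total(self) -> int:
        return self.lus_exam_rater1.total


# Severity-conditional probabilities of each LUS component level (0, 1, 2),
# per component, calibrated so the mixture over the default severity
# distribution reproduces the published overall finding frequencies and an
# agreement level in the study's range.
_DEFAULT_LUS_TABLES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "mild": (
        (0.68, 0.29, 0.03),  # anterolateral
        (0.20, 0.68, 0.12),  # posterior interstitial
        (0.82, 0.18, 0.00),  # extension
        (0.70, 0.27, 0.03),  # consolidation
    ),
    "moderate": (
        (0.28, 0.52, 0.20),
        (0.02, 0.48, 0.50),
        (0.08, 0.62, 0.30),
        (0.15, 0.42, 0.43),
    ),
    "severe": (
        (0.05, 0.35, 0.60),
        (0.00, 0.20, 0.80),
        (0.00, 0.25, 0.75),
        (0.00, 0.30, 0.70),
    ),
}

# P(oxygen required | LUS total 0..8): monotone step calibrated to an
# overall prevalence near 27 % (29/106) with the ">3" rule at ~97/97 sens/spec.
_DEFAULT_OXYGEN_GIVEN_TOTAL = (
    0.005, 0.005, 0.005, 0.04, 0.86, 0.95, 0.96, 0.97, 0.97,
)


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; defaults encode the study's published margins."""

    n_cases: int = 106
    n_controls: int = 25
    severity_probs: tuple[float, float, float] = (76 / 106, 27 / 106, 3 / 106)
    srv_prevalence: float = 73 / 106
    oxygen_given_total: tuple[float, ...] = _DEFAULT_OXYGEN_GIVEN_TOTAL
    conditional_lus_tables: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_LUS_TABLES)
    )
    rater2_stay_prob: float = 0.90
    control_b_line_prob: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        sp = np.asarray(self.severity_probs, dtype=float)
        if sp.shape != (3,) or (sp < 0).any() or abs(sp.sum() - 1) > 1e-9:
            raise ValueError("severity_probs must be 3 non-negative values summing to 1")
        if len(self.oxygen_given_total) != 9:
            raise ValueError("oxygen_given_total must have one entry per total 0..8")
        probs = np.asarray(self.oxygen_given_total, dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("oxygen_given_total entries must be probabilities")
        if (np.diff(probs) < 0).any():
            raise ValueError("oxygen_given_total must be non-decreasing in the total")
        for grade, tables in self.conditional_lus_tables.items():
            if grade not in ("mild", "moderate", "severe"):
                raise ValueError(f"unknown severity grade {grade!r}")
            for tab in tables:
                t = np.asarray(tab, dtype=float)
                if t.shape != (3,) or (t < 0).any() or abs(t.sum() - 1) > 1e-9:
                    raise ValueError(
                        f"each component table must be 3 probabilities summing to 1, got {tab}"
                    )
        for p, name in (
            (self.srv_prevalence, "srv_prevalence"),
            (self.rater2_stay_prob, "rater2_stay_prob"),
            (self.control_b_line_prob, "control_b_line_prob"),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


DEFAULT_PARAMS = CohortParams()

_GRADE_NAMES = {1: "mild", 2: "moderate", 3: "severe"}
_CLINICAL_BANDS = {1: (1, 4), 2: (5, 8), 3: (9, 12)}
_LUS_BANDS = {0: (0, 0), 1: (1, 3), 2: (4, 6), 3: (7, 8)}


def _tuples_with_total_in(levels: int, lo: int, hi: int) -> np.ndarray:
    combos = [
        c
        for c in itertools.product(range(levels), repeat=4)
        if lo <= sum(c) <= hi
    ]
    return np.array(combos, dtype=np.int64)


_CLINICAL_TUPLES = {g: _tuples_with_total_in(4, *b) for g, b in _CLINICAL_BANDS.items()}
_LUS_TUPLES = {g: _tuples_with_total_in(3, *b) for g, b in _LUS_BANDS.items()}


def _neighbour_grades(grade: int) -> tuple[int, ...]:
    return tuple(g for g in (grade - 1, grade + 1) if 0 <= g <= 3)


def generate_cohort(params: CohortParams = DEFAULT_PARAMS) -> list[CohortRecord]:
    """Draw a synthetic cohort; deterministic for a given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    records: list[CohortRecord] = []

    for i in range(params.n_cases):
        severity = int(rng.choice((1, 2, 3), p=params.severity_probs))
        clin_items = _CLINICAL_TUPLES[severity][
            rng.integers(len(_CLINICAL_TUPLES[severity]))
        ]
        clinical = ClinicalAssessment(*map(int, clin_items))

        tables = params.conditional_lus_tables[_GRADE_NAMES[severity]]
        lus_items = [int(rng.choice(3, p=tab)) for tab in tables]
        exam1 = LUSExam(*lus_items)
        grade1 = int(grade_lus(exam1.total))

        if rng.random() < params.rater2_stay_prob:
            exam2 = exam1
        else:
            neighbours = _neighbour_grades(grade1)
            grade2 = int(neighbours[rng.integers(len(neighbours))])
            choices = _LUS_TUPLES[grade2]
            exam2 = LUSExam(*map(int, choices[rng.integers(len(choices))]))

        oxygen = bool(rng.random() < params.oxygen_given_total[exam1.total])
        srv = bool(rng.random() < params.srv_prevalence)
        records.append(
            CohortRecord(
                patient_id=f"case_{i:05d}",
                age_days=int(rng.integers(9, 240)),
                is_control=False,
                clinical_items=clinical,
                lus_exam_rater1=exam1,
                lus_exam_rater2=exam2,
                oxygen_required=oxygen,
                srv_positive=srv,
                sex="m" if rng.random() < 0.56 else "f",
                delivery="vaginal" if rng.random() < 0.60 else "cesarean",
                breastfed=bool(rng.random() < 0.59),
                preterm=bool(rng.random() < 7 / 106),
                isolated_b_line=False,
                resolved_at_discharge=True,
            )
        )

    normal_clin = ClinicalAssessment(0, 0, 0, 0)
    normal_exam = LUSExam(0, 0, 0, 0)
    for i in range(params.n_controls):
        records.append(
            CohortRecord(
                patient_id=f"ctrl_{i:05d}",
                age_days=int(rng.integers(32, 161)),
                is_control=True,
                clinical_items=normal_clin,
                lus_exam_rater1=normal_exam,
                lus_exam_rater2=normal_exam,
                oxygen_required=False,
                srv_positive=False,
                sex="m" if rng.random() < 11 / 25 else "f",
                delivery="vaginal" if rng.random() < 0.60 else "cesarean",
                breastfed=bool(rng.random() < 0.59),
                preterm=bool(rng.random() < 1 / 25),
                isolated_b_line=bool(rng.random() < params.control_b_line_prob),
                resolved_at_discharge=True,
            )
        )
    return records
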
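"""Orchestration: cohort CSV I/O, the full analysis battery, and reproduction
of the source study's printed statistics from its packaged counts.

A cohort CSV has one row per infant. Two schema modes are accepted:

``precoded_items``
    All eight score items already coded (clinical 0-3, LUS 0-2), columns
    ``rr_item, dyspnea_item, accessory_item, auscultation_item`` and
    ``r{1,2}_anterolateral, r{1,2}_posterior_interstitial,
    r{1,2}_extension, r{1,2}_consolidation``.

``raw_observations``
    Mechanically codable observations are given raw instead:
    ``respiratory_rate`` (breaths/min), ``r{1,2}_extension_spaces``
    (bilaterally involved posterior intercostal spaces) and
    ``r{1,2}_consolidation_cm`` (largest posterior consolidation, empty =
    absent). Dyspnea, accessory-muscle, auscultation, anterolateral and
    posterior-interstitial codes remain pre-coded: they are multi-sign
    judgments with no numeric raw form.

Shared columns: ``patient_id, age_days, is_control, oxygen_required,
srv_positive`` (booleans as true/false or 1/0); optional demographics
``sex, delivery, breastfed, preterm, isolated_b_line,
resolved_at_discharge``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    DegenerateMarginalsError,
    KappaResult,
    cohen_kappa,
    confusion_from_pairs,
    expected_agreement,
    kappa_analysis,
    kappa_se0,
    kappa_z_test,
)
from .cohort import CohortRecord
from .diagnostics import (
    ProportionEstimate,
    SmallExpectedCountWarning,
    TwoByTwo,
    UndefinedMetricError,
    clopper_pearson_interval,
    npv as _npv,
    pearson_chi2_2x2,
    ppv as _ppv,
    sensitivity,
    specificity,
    two_by_two_from_cohort,
    two_by_two_from_groups,
    wilson_interval,
)
from .fixtures import StudyFixtures, study_fixtures
from .scoring import (
    ClinicalAssessment,
    LUSExam,
    ScoringConfig,
    DEFAULT_CONFIG,
    encode_consolidation,
    encode_extension,
    encode_respiratory_rate,
    grade_lus,
    score_clinical,
    score_lus,
)

__all__ = [
    "AnalysisReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_analysis",
    "reproduce_study",
]


class CohortSchemaError(ValueError):
    """A cohort CSV row violates the column dictionary."""


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool(value: Any, row: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise CohortSchemaError(
            f"row {row}, column {column!r}: malformed boolean {value!r}"
        )
    return _BOOL_MAP[key]


def _parse_item(value: Any, hi: int, row: int, column: str) -> int:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise CohortSchemaError(
            f"row {row}, column {column!r}: not an integer: {value!r}"
        ) from None
    if not 0 <= iv <= hi:
        raise CohortSchemaError(
            f"row {row}, column {column!r}: item {iv} outside 0..{hi}"
        )
    return iv


_SHARED_COLUMNS = ["patient_id", "age_days", "is_control", "oxygen_required", "srv_positive"]
_PRECODED_CLINICAL = ["rr_item", "dyspnea_item", "accessory_item", "auscultation_item"]
_LUS_SUFFIXES = ["anterolateral", "posterior_interstitial", "extension", "consolidation"]


def read_cohort_csv(
    path: str | Path,
    schema_mode: str = "precoded_items",
    config: ScoringConfig = DEFAULT_CONFIG,
) -> list[CohortRecord]:
    """Read and validate a cohort CSV into records.

    Errors name the offending row (1-based data row) and column.
    """
    if schema_mode not in ("precoded_items", "raw_observations"):
        raise ValueError(f"unknown schema_mode {schema_mode!r}")
    df = pd.read_csv(path, dtype=str).fillna("")
    required = list(_SHARED_COLUMNS)
    if schema_mode == "precoded_items":
        required += _PRECODED_CLINICAL
        required += [f"r{r}_{s}" for r in (1, 2) for s in _LUS_SUFFIXES]
    else:
        required += ["respiratory_rate"] + _PRECODED_CLINICAL[1:]
        for r in (1, 2):
            required += [
                f"r{r}_anterolateral",
                f"r{r}_posterior_interstitial",
                f"r{r}_extension_spaces",
                f"r{r}_consolidation_cm",
            ]
    missing = sorted(set(required) - set(df.columns))
    if missing:
        raise CohortSchemaError(f"missing required columns: {missing}")

    records: list[CohortRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        if schema_mode == "precoded_items":
            clin = ClinicalAssessment(
                *(_parse_item(row[c], 3, i, c) for c in _PRECODED_CLINICAL)
            )
            exams = []
            for r in (1, 2):
                exams.append(
                    LUSExam(*(_parse_item(row[f"r{r}_{s}"], 2, i, f"r{r}_{s}")
                              for s in _LUS_SUFFIXES))
                )
        else:
            try:
                rr_item = encode_respiratory_rate(float(row["respiratory_rate"]), config)
            except ValueError as exc:
                raise CohortSchemaError(
                    f"row {i}, column 'respiratory_rate': {exc}"
                ) from None
            clin = ClinicalAssessment(
                rr_item,
                *(_parse_item(row[c], 3, i, c) for c in _PRECODED_CLINICAL[1:]),
            )
            exams = []
            for r in (1, 2):
                try:
                    ext = encode_extension(
                        int(row[f"r{r}_extension_spaces"]), config
                    )
                    raw_size = row[f"r{r}_consolidation_cm"].strip()
                    cons = encode_consolidation(
                        None if raw_size == "" else float(raw_size)
                    )
                except ValueError as exc:
                    raise CohortSchemaError(f"row {i}: {exc}") from None
                exams.append(
                    LUSExam(
                        _parse_item(row[f"r{r}_anterolateral"], 2, i, f"r{r}_anterolateral"),
                        _parse_item(
                            row[f"r{r}_posterior_interstitial"], 2, i,
                            f"r{r}_posterior_interstitial",
                        ),
                        ext,
                        cons,
                    )
                )
        try:
            age = int(row["age_days"])
        except ValueError:
            raise CohortSchemaError(
                f"row {i}, column 'age_days': not an integer: {row['age_days']!r}"
            ) from None
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                age_days=age,
                is_control=_parse_bool(row["is_control"], i, "is_control"),
                clinical_items=clin,
                lus_exam_rater1=exams[0],
                lus_exam_rater2=exams[1],
                oxygen_required=_parse_bool(row["oxygen_required"], i, "oxygen_required"),
                srv_positive=_parse_bool(row["srv_positive"], i, "srv_positive"),
                sex=str(row.get("sex", "f") or "f"),
                delivery=str(row.get("delivery", "vaginal") or "vaginal"),
                breastfed=_parse_bool(row.get("breastfed", "true") or "true", i, "breastfed"),
                preterm=_parse_bool(row.get("preterm", "false") or "false", i, "preterm"),
                isolated_b_line=_parse_bool(
                    row.get("isolated_b_line", "false") or "false", i, "isolated_b_line"
                ),
                resolved_at_discharge=_parse_bool(
                    row.get("resolved_at_discharge", "true") or "true",
                    i, "resolved_at_discharge",
                ),
            )
        )
    return records


def write_cohort_csv(records: list[CohortRecord], path: str | Path) -> None:
    """Write records in the ``precoded_items`` column dictionary."""
    rows = []
    for rec in records:
        row: dict[str, Any] = {
            "patient_id": rec.patient_id,
            "age_days": rec.age_days,
            "is_control": rec.is_control,
        }
        for col, item in zip(_PRECODED_CLINICAL, rec.clinical_items.items):
            row[col] = item
        for r, exam in ((1, rec.lus_exam_rater1), (2, rec.lus_exam_rater2)):
            for suffix, item in zip(_LUS_SUFFIXES, exam.items):
                row[f"r{r}_{suffix}"] = item
        row.update(
            oxygen_required=rec.oxygen_required,
            srv_positive=rec.srv_positive,
            sex=rec.sex,
            delivery=rec.delivery,
            breastfed=rec.breastfed,
            preterm=rec.preterm,
            isolated_b_line=rec.isolated_b_line,
            resolved_at_discharge=rec.resolved_at_discharge,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Full analysis battery


@dataclass(frozen=True)
class AnalysisReport:
    """All statistics of one cohort analysis, recomputable from stored inputs."""

    n_cases: int
    n_controls: int
    score_summaries: dict[str, dict[str, int]]
    kappa_results: dict[str, KappaResult]
    oxygen_table: TwoByTwo
    oxygen_metrics: dict[str, ProportionEstimate]
    group_comparisons: list[dict[str, Any]]
    config_echo: dict[str, Any]
    provenance: dict[str, Any]

    def to_json(self, indent: int = 2) -> str:
        def default(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(f"not JSON-serialisable: {type(obj)}")

        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True,
                          default=default)


_FINDING_LEVELS = {
    "anterolateral": ("normal", "interstitial", "consolidation"),
    "posterior_interstitial": ("none", "focal", "confluent"),
    "extension": ("lt6", "6to12", "gt12"),
    "consolidation": ("none", "subcm", "ge1cm"),
}


def _case_strata(records: list[CohortRecord]) -> dict[str, tuple[list, list]]:
    cases = [r for r in records if not r.is_control]
    mild = [r for r in cases if score_clinical(r.clinical_items).grade == 1]
    modsev = [r for r in cases if score_clinical(r.clinical_items).grade >= 2]
    no_ox = [r for r in cases if not r.oxygen_required]
    ox = [r for r in cases if r.oxygen_required]
    srv_neg = [r for r in cases if not r.srv_positive]
    srv_pos = [r for r in cases if r.srv_positive]
    return {
        "mild_vs_modsev": (mild, modsev),
        "no_oxygen_vs_oxygen": (no_ox, ox),
        "srv_neg_vs_pos": (srv_neg, srv_pos),
    }


def run_analysis(
    records: list[CohortRecord],
    config: ScoringConfig = DEFAULT_CONFIG,
    ci_method: str = "wilson",
    seed: int | None = None,
) -> AnalysisReport:
    """Score a cohort and compute the full agreement/diagnostics battery.

    Degenerate strata (an empty comparison group, or a finding absent in
    both groups) are skipped with a warning entry, not a failure.
    """
    if not records:
        raise ValueError("cannot analyse an empty cohort")
    cases = [r for r in records if not r.is_control]

    grade_names = ("normal", "mild", "moderate", "severe")
    summaries: dict[str, dict[str, int]] = {}
    clin_grades = [int(score_clinical(r.clinical_items).grade) for r in records]
    r1_grades = [int(score_lus(r.lus_exam_rater1).grade) for r in records]
    r2_grades = [int(score_lus(r.lus_exam_rater2).grade) for r in records]
    for name, grades in (
        ("clinical", clin_grades),
        ("lus_rater1", r1_grades),
        ("lus_rater2", r2_grades),
    ):
        summaries[name] = {
            g: sum(1 for x in grades if x == i) for i, g in enumerate(grade_names)
        }

    kappas: dict[str, KappaResult] = {}
    for label, (a, b) in (
        ("clinical_vs_rater1", (clin_grades, r1_grades)),
        ("rater1_vs_rater2", (r1_grades, r2_grades)),
    ):
        try:
            cm = confusion_from_pairs(list(zip(a, b)), categories=(0, 1, 2, 3))
            kappas[label] = kappa_analysis(cm)
        except DegenerateMarginalsError:
            warnings.warn(f"agreement {label}: degenerate marginals, skipped")

    oxygen_source = cases if cases else records
    table = two_by_two_from_cohort(oxygen_source, config)
    metrics: dict[str, ProportionEstimate] = {}
    for name, fn in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("ppv", _ppv),
        ("npv", _npv),
    ):
        try:
            metrics[name] = fn(table, ci_method=ci_method)
        except UndefinedMetricError as exc:
            warnings.warn(f"oxygen diagnostics: {exc}; metric omitted")

    comparisons: list[dict[str, Any]] = []
    strata = _case_strata(records)
    for component, levels in _FINDING_LEVELS.items():
        for code, level in enumerate(levels):
            for comparison, (grp_a, grp_b) in strata.items():
                entry: dict[str, Any] = {
                    "finding": f"{component}_{level}",
                    "comparison": comparison,
                }
                if not grp_a or not grp_b:
                    entry["skipped"] = "empty stratum"
                    comparisons.append(entry)
                    continue
                pos_a = sum(
                    1 for r in grp_a
                    if getattr(r.lus_exam_rater1, f"{component}_item") == code
                )
                pos_b = sum(
                    1 for r in grp_b
                    if getattr(r.lus_exam_rater1, f"{component}_item") == code
                )
                counts = two_by_two_from_groups(pos_a, len(grp_a), pos_b, len(grp_b))
                entry.update(
                    pos_a=pos_a, n_a=len(grp_a), pos_b=pos_b, n_b=len(grp_b)
                )
                if (counts.sum(axis=0) == 0).any():
                    entry["skipped"] = "finding level absent or universal in both groups"
                    comparisons.append(entry)
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", SmallExpectedCountWarning)
                    res = pearson_chi2_2x2(counts)
                entry.update(chi2=res.statistic, df=res.df, p_value=res.p_value)
                comparisons.append(entry)

    return AnalysisReport(
        n_cases=len(cases),
        n_controls=len(records) - len(cases),
        score_summaries=summaries,
        kappa_results=kappas,
        oxygen_table=table,
        oxygen_metrics=metrics,
        group_comparisons=comparisons,
        config_echo=dataclasses.asdict(config),
        provenance={"package": "luscore", "version": __version__, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Reproduction of the published statistics


def reproduce_study(fixtures: StudyFixtures | None = None) -> pd.DataFrame:
    """Recompute every reproducible printed statistic from the fixture counts.

    Returns one row per statistic: ``target_id``, ``computed``, ``printed``
    (both on the printed scale), and ``match`` — computed within 1 % of
    printed, or within one unit of the last printed decimal, whichever is
    looser (the source truncates rather than rounds its statistics, so a
    printed "2.3" covers [2.3, 2.4)). Fixture rows flagged as internally
    inconsistent in the source are excluded.
    """
    fx = fixtures if fixtures is not None else study_fixtures()
    rows: list[dict[str, Any]] = []

    def add(target_id: str, computed: float, printed: float) -> None:
        tol = max(0.01 * abs(printed), 2 * _half_ulp(printed))
        rows.append(
            {
                "target_id": target_id,
                "computed": computed,
                "printed": printed,
                "match": abs(computed - printed) <= tol,
            }
        )

    for idx, rp in enumerate(fx.rater_pairs, start=1):
        po = rp.diagonal_total / rp.n
        pe = expected_agreement(rp.row_marginals, rp.col_marginals, rp.n)
        kappa = cohen_kappa(po, pe)
        se0 = kappa_se0(rp.row_marginals, rp.col_marginals, rp.n)
        z, _ = kappa_z_test(kappa, se0)
        add(f"kappa{idx}_observed_agreement_pct", 100 * po,
            rp.printed_observed_agreement_pct)
        add(f"kappa{idx}_expected_agreement_pct", 100 * pe,
            rp.printed_expected_agreement_pct)
        add(f"kappa{idx}_kappa", kappa, rp.printed_kappa)
        add(f"kappa{idx}_se0", se0, rp.printed_se0)
        if not rp.z_discrepant:
            add(f"kappa{idx}_z", z, rp.printed_z)

    t = fx.oxygen_2x2
    printed = fx.oxygen_printed
    add("oxygen_sensitivity_pct", 100 * sensitivity(t).point,
        printed["printed_sensitivity_pct"])
    add("oxygen_specificity_pct", 100 * specificity(t).point,
        printed["printed_specificity_pct"])
    add("oxygen_ppv_pct", 100 * t.tp / (t.tp + t.fp), printed["printed_ppv_pct"])
    add("oxygen_npv_pct", 100 * t.tn / (t.tn + t.fn), printed["printed_npv_pct"])
    spec_ci = wilson_interval(t.tn, t.tn + t.fp)
    add("oxygen_specificity_ci_low_pct", 100 * spec_ci[0],
        printed["printed_specificity_ci_pct"][0])
    add("oxygen_specificity_ci_high_pct", 100 * spec_ci[1],
        printed["printed_specificity_ci_pct"][1])
    sens_cp = clopper_pearson_interval(t.tp, t.tp + t.fn)
    add("oxygen_sensitivity_ci_low_pct", 100 * sens_cp[0],
        printed["printed_sensitivity_ci_pct"][0])

    for gc in fx.group_comparisons:
        if gc.discrepant:
            continue
        counts = two_by_two_from_groups(gc.pos_a, gc.n_a, gc.pos_b, gc.n_b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            res = pearson_chi2_2x2(counts)
        add(f"chi2_{gc.fixture_id}", res.statistic, gc.printed_chi2)

    return pd.DataFrame(rows)


def _half_ulp(printed: float) -> float:
    """Half a unit in the last printed decimal place (e.g. 44.3 -> 0.05)."""
    text = repr(float(printed))
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 0.5 * 10 ** (-decimals)
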
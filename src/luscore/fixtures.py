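"""Packaged fixtures: the published counts of the bronchiolitis LUS study.

The source study released no patient-level data, only marginal counts and
2x2 slices. These fixtures encode every printed count needed to recompute
its headline statistics:

* the severity-grade marginals of each rater pair (with the printed
  agreement summaries),
* the reconstructed oxygen-need 2x2 table — the unique non-negative
  integer table with n = 106, 29 oxygen-requiring infants, and the printed
  sensitivity (96.6 %) and specificity (98.7 %), namely TP=28, FP=1, FN=1,
  TN=76,
* every group-comparison row of the finding-frequency tables, with the
  chi-square value printed beside it.

Rows whose printed statistic is inconsistent with their own printed counts
carry a ``discrepant``/``z_discrepant`` flag and are excluded from
reproduction checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .diagnostics import TwoByTwo

__all__ = [
    "RaterPairFixture",
    "GroupComparisonFixture",
    "StudyFixtures",
    "study_fixtures",
]


@dataclass(frozen=True)
class RaterPairFixture:
    """Published marginals and agreement summary for one rater pair."""

    fixture_id: str
    rater_a: str
    rater_b: str
    categories: tuple[str, ...]
    row_marginals: tuple[int, ...]
    col_marginals: tuple[int, ...]
    n: int
    diagonal_total: int
    printed_observed_agreement_pct: float
    printed_expected_agreement_pct: float
    printed_kappa: float
    printed_se0: float
    printed_z: float
    z_discrepant: bool


@dataclass(frozen=True)
class GroupComparisonFixture:
    """One published finding-frequency row: counts in two groups + printed chi2."""

    fixture_id: str
    table: int
    finding: str
    comparison: str
    pos_a: int
    n_a: int
    pos_b: int
    n_b: int
    printed_chi2: float
    discrepant: bool


@dataclass(frozen=True)
class StudyFixtures:
    rater_pairs: tuple[RaterPairFixture, ...]
    oxygen_2x2: TwoByTwo
    oxygen_printed: dict
    group_comparisons: tuple[GroupComparisonFixture, ...]

    def rater_pair(self, fixture_id: str) -> RaterPairFixture:
        for rp in self.rater_pairs:
            if rp.fixture_id == fixture_id:
                return rp
        raise KeyError(fixture_id)

    def comparison(self, fixture_id: str) -> GroupComparisonFixture:
        for gc in self.group_comparisons:
            if gc.fixture_id == fixture_id:
                return gc
        raise KeyError(fixture_id)


def study_fixtures() -> StudyFixtures:
    """Load the packaged fixture bundle."""
    root = resources.files("luscore") / "data"
    agreement = json.loads((root / "agreement_fixtures.json").read_text())
    categories = tuple(agreement["categories"])
    pairs = tuple(
        RaterPairFixture(
            fixture_id=rp["fixture_id"],
            rater_a=rp["rater_a"],
            rater_b=rp["rater_b"],
            categories=categories,
            row_marginals=tuple(rp["row_marginals"]),
            col_marginals=tuple(rp["col_marginals"]),
            n=rp["n"],
            diagonal_total=rp["diagonal_total"],
            printed_observed_agreement_pct=rp["printed_observed_agreement_pct"],
            printed_expected_agreement_pct=rp["printed_expected_agreement_pct"],
            printed_kappa=rp["printed_kappa"],
            printed_se0=rp["printed_se0"],
            printed_z=rp["printed_z"],
            z_discrepant=rp["z_discrepant"],
        )
        for rp in agreement["rater_pairs"]
    )
    ox = agreement["oxygen_2x2"]
    oxygen = TwoByTwo(tp=ox["tp"], fp=ox["fp"], fn=ox["fn"], tn=ox["tn"])

    with (root / "group_comparisons.csv").open() as fh:
        rows = pd.read_csv(fh)
    comparisons = tuple(
        GroupComparisonFixture(
            fixture_id=r.fixture_id,
            table=int(r.table),
            finding=r.finding,
            comparison=r.comparison,
            pos_a=int(r.pos_a),
            n_a=int(r.n_a),
            pos_b=int(r.pos_b),
            n_b=int(r.n_b),
            printed_chi2=float(r.printed_chi2),
            discrepant=bool(r.discrepant),
        )
        for r in rows.itertuples(index=False)
    )
    return StudyFixtures(
        rater_pairs=pairs,
        oxygen_2x2=oxygen,
        oxygen_printed={k: v for k, v in ox.items() if k.startswith("printed")},
        group_comparisons=comparisons,
    )
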
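"""Dyadic mouse-contest scoring and the dominance-inheritance cross table.

Each contest pairs two F1 hybrid males sharing a maternal strain but sired
by different paternal strains (a diallel cross).  Over repeated
observations the dominant male is identified by asymmetry in agonistic
behaviour: strictly more attacks AND strictly fewer submissive poses than
its opponent (the conjunctive rule; an attacks-only rule is available).
Per-maternal-strain counts of which sire's son dominated are tested with
the uncorrected equal-split χ².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .errors import DataError, InputError
from .stats import TestResult, chi2_equal_split

MATERNAL_STRAINS = ("PT", "DD", "C57BL/6J", "YT", "A/He")
PATERNAL_STRAINS = ("BALB/cLac", "CBA/Lac")

#: Dominance rules: conjunctive attacks-and-poses (default) or attacks only.
RULES = ("attacks_and_poses", "attacks_only")


class Outcome(str, Enum):
    A_DOMINANT = "a_dominant"
    B_DOMINANT = "b_dominant"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Observation:
    """Counts from one timed observation of a pair."""

    attacks_a: int
    attacks_b: int
    submissive_a: int
    submissive_b: int

    def __post_init__(self) -> None:
        if min(self.attacks_a, self.attacks_b, self.submissive_a, self.submissive_b) < 0:
            raise InputError("negative behaviour count")


@dataclass(frozen=True)
class ContestRecord:
    """One dyad: maternal strain, the two sires, and its observations."""

    pair_id: str
    maternal_strain: str
    male_a_paternal: str
    male_b_paternal: str
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if self.maternal_strain not in MATERNAL_STRAINS:
            raise DataError(f"{self.pair_id}: unknown maternal strain "
                            f"{self.maternal_strain!r}")
        for p in (self.male_a_paternal, self.male_b_paternal):
            if p not in PATERNAL_STRAINS:
                raise DataError(f"{self.pair_id}: unknown paternal strain {p!r}")
        if self.male_a_paternal == self.male_b_paternal:
            raise DataError(f"{self.pair_id}: both males share a paternal strain")
        if not self.observations:
            raise DataError(f"{self.pair_id}: no observations")


def score_contest(record: ContestRecord, rule: str = "attacks_and_poses") -> Outcome:
    """Identify the pair's dominant male from pooled observation totals.

    Under the conjunctive rule male a is dominant iff it has strictly more
    total attacks AND strictly fewer total submissive poses; any tie or
    disagreement between the two measures is unresolved.
    """
    if rule not in RULES:
        raise InputError(f"unknown rule {rule!r}; expected one of {RULES}")
    atk_a = sum(o.attacks_a for o in record.observations)
    atk_b = sum(o.attacks_b for o in record.observations)
    sub_a = sum(o.submissive_a for o in record.observations)
    sub_b = sum(o.submissive_b for o in record.observations)
    if rule == "attacks_only":
        if atk_a > atk_b:
            return Outcome.A_DOMINANT
        if atk_b > atk_a:
            return Outcome.B_DOMINANT
        return Outcome.UNRESOLVED
    if atk_a > atk_b and sub_a < sub_b:
        return Outcome.A_DOMINANT
    if atk_b > atk_a and sub_b < sub_a:
        return Outcome.B_DOMINANT
    return Outcome.UNRESOLVED


@dataclass
class CrossRow:
    """Dominant counts for one maternal strain, by paternal strain."""

    maternal_strain: str
    n_dominant: dict[str, int]
    test: TestResult


@dataclass
class CrossTable:
    """Per-maternal-strain dominance counts with χ² tests and totals."""

    paternal_strains: tuple[str, str]
    rows: dict[str, CrossRow]
    total: CrossRow
    unresolved: list[str] = field(default_factory=list)

    def counts(self, maternal: str) -> tuple[int, int]:
        row = self.total if maternal == "TOTAL" else self.rows[maternal]
        return tuple(row.n_dominant[p] for p in self.paternal_strains)


def tabulate_crosses(
    records: Iterable[ContestRecord],
    rule: str = "attacks_and_poses",
    paternal_strains: Sequence[str] = PATERNAL_STRAINS,
) -> CrossTable:
    """Score every contest and build the per-strain dominance cross table.

    Unresolved pairs are excluded from the counts and listed in
    ``CrossTable.unresolved``.
    """
    p1, p2 = paternal_strains
    counts: dict[str, dict[str, int]] = {}
    unresolved: list[str] = []
    for rec in records:
        outcome = score_contest(rec, rule=rule)
        if outcome is Outcome.UNRESOLVED:
            unresolved.append(rec.pair_id)
            continue
        sire = (rec.male_a_paternal if outcome is Outcome.A_DOMINANT
                else rec.male_b_paternal)
        row = counts.setdefault(rec.maternal_strain, {p1: 0, p2: 0})
        row[sire] += 1
    rows = {}
    tot = {p1: 0, p2: 0}
    for strain in MATERNAL_STRAINS:
        if strain not in counts:
            continue
        c = counts[strain]
        tot[p1] += c[p1]
        tot[p2] += c[p2]
        rows[strain] = CrossRow(
            maternal_strain=strain,
            n_dominant=dict(c),
            test=chi2_equal_split(c[p1], c[p2]),
        )
    if tot[p1] + tot[p2] == 0:
        raise DataError("no resolved contests to tabulate")
    total = CrossRow(
        maternal_strain="TOTAL",
        n_dominant=dict(tot),
        test=chi2_equal_split(tot[p1], tot[p2]),
    )
    return CrossTable(
        paternal_strains=(p1, p2),
        rows=rows,
        total=total,
        unresolved=unresolved,
    )
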
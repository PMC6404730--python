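"""The basic decision-making rule and dichotomy tallies.

A significant expression shift becomes a candidate marker by combining it
with the gene's curated phenotype polarity: if protein excess is a known
marker of dominance-like behaviour (low pain sensitivity, fast post-injury
recovery, aggressive/risk-seeking phenotypes), then a SNP predicted to
cause overexpression marks a tendency to social dominance and one causing
underexpression marks subordination — and vice versa for genes whose
excess marks subordination-like phenotypes.

The tally reproduces the per-system dichotomy table shape: N_RES
significant SNPs split as N↑ (dominance) vs N↓ (subordination) and as
N> (overexpression) vs N< (underexpression).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .errors import DataError
from .variants import ComparisonResult, Decision

SYSTEMS = ("neuropeptidergic", "non-neuropeptidergic", "neurotrophinergic")
TOTAL_LABEL = "TOTAL"


class Polarity(str, Enum):
    EXCESS_MARKS_DOMINANCE = "excess_marks_dominance"
    EXCESS_MARKS_SUBORDINATION = "excess_marks_subordination"


class Marker(str, Enum):
    DOMINANCE = "dominance"
    SUBORDINATION = "subordination"
    NONE = "none"


@dataclass(frozen=True)
class GeneAnnotation:
    """Curated body-system class and marker polarity of one gene."""

    gene_id: str
    system: str
    polarity: Polarity
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise DataError(
                f"{self.gene_id}: unknown system {self.system!r}; "
                f"expected one of {SYSTEMS}"
            )


@dataclass
class DichotomyCounts:
    """One row of the dichotomy table: N_RES, N↑, N↓, N>, N<."""

    system: str
    n_res: int = 0
    n_dom: int = 0
    n_sub: int = 0
    n_over: int = 0
    n_under: int = 0

    def validate(self) -> None:
        if min(self.n_res, self.n_dom, self.n_sub, self.n_over, self.n_under) < 0:
            raise DataError("negative count")
        if self.n_res != self.n_over + self.n_under:
            raise DataError("n_res != n_over + n_under")
        if self.n_res != self.n_dom + self.n_sub:
            raise DataError("n_res != n_dom + n_sub")


def classify_marker(decision: Decision, polarity: Polarity) -> Marker:
    """Apply the decision-making rule to one (direction, polarity) pair."""
    if decision is Decision.INSIGNIFICANT:
        return Marker.NONE
    excess_dominates = polarity is Polarity.EXCESS_MARKS_DOMINANCE
    over = decision is Decision.OVEREXPRESSION
    return Marker.DOMINANCE if over == excess_dominates else Marker.SUBORDINATION


def tally(
    results: Iterable[tuple[ComparisonResult, GeneAnnotation | None]],
) -> dict[str, DichotomyCounts]:
    """Per-system and total dichotomy counts over annotated comparisons.

    Significant results must carry an annotation; insignificant ones
    contribute nothing (genes with no significant SNPs yield zero rows).
    """
    counts = {s: DichotomyCounts(system=s) for s in SYSTEMS}
    counts[TOTAL_LABEL] = DichotomyCounts(system=TOTAL_LABEL)
    unannotated: list[str] = []
    for result, annotation in results:
        if result.decision is Decision.INSIGNIFICANT:
            continue
        if annotation is None:
            unannotated.append(result.gene_id)
            continue
        marker = classify_marker(result.decision, annotation.polarity)
        for row in (counts[annotation.system], counts[TOTAL_LABEL]):
            row.n_res += 1
            if result.decision is Decision.OVEREXPRESSION:
                row.n_over += 1
            else:
                row.n_under += 1
            if marker is Marker.DOMINANCE:
                row.n_dom += 1
            else:
                row.n_sub += 1
    if unannotated:
        raise DataError(
            "significant results without gene annotation: "
            + ", ".join(sorted(set(unannotated)))
        )
    for row in counts.values():
        row.validate()
    return counts
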
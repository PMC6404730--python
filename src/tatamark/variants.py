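"""Allele comparison for core-promoter SNPs.

A variant is applied to the promoter to obtain the minor-allele sequence;
both alleles are scored with the affinity model; the difference is tested
with the Fisher Z-score

    Z = |ln(K_D^min / K_D^wt)| / sqrt(δ_min² + δ_wt²)
      = |(−ln K_D^wt) − (−ln K_D^min)| / sqrt(δ_wt² + δ_min²)

whose two-tailed standard-normal p-value gives the confidence α = 1 − p.
A significant increase of the minor allele's affinity (−ln K_D) is called
overexpression of the gene (tighter TBP binding, more transcription), a
significant decrease underexpression.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from scipy.stats import norm

from .affinity import (
    AffinityEstimate,
    ModelConfig,
    PromoterRecord,
    estimate_affinity,
    normalize_sequence,
)
from .errors import DataError, InputError


class Decision(str, Enum):
    """Predicted direction of the expression shift caused by the minor allele."""

    OVEREXPRESSION = "overexpression"
    UNDEREXPRESSION = "underexpression"
    INSIGNIFICANT = "insignificant"


#: Heuristic prediction rank ρ, from best (A) to worst (E); lower bin
#: boundaries on α.
RANK_BINS: tuple[tuple[str, float], ...] = (
    ("A", 0.9999),
    ("B", 0.999),
    ("C", 0.99),
    ("D", 0.95),
)


@dataclass(frozen=True)
class SnpRecord:
    """One promoter variant: rs-style id, gene, TSS-relative offset, alleles."""

    variant_id: str
    gene_id: str
    offset: int
    wt_allele: str
    min_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt_allele", normalize_sequence(self.wt_allele))
        object.__setattr__(self, "min_allele", normalize_sequence(self.min_allele))
        if not self.wt_allele or not self.min_allele:
            raise InputError(f"{self.variant_id}: empty allele")


@dataclass(frozen=True)
class ComparisonResult:
    """Per-SNP allele comparison: Z, p, α, direction decision Δ and rank ρ."""

    variant_id: str
    gene_id: str
    wt: AffinityEstimate
    mn: AffinityEstimate
    z: float
    p_value: float
    alpha: float
    decision: Decision
    rank: str


def apply_variant(
    promoter: PromoterRecord,
    snp: SnpRecord,
    flank_5prime: str | None = None,
) -> PromoterRecord:
    """Return the minor-allele promoter in the same coordinate frame.

    Substitutions preserve length.  Indels change the length of the edited
    sequence, which is then re-anchored at its 3' (TSS-proximal) end: a net
    deletion pulls additional upstream bases in from ``flank_5prime`` (its
    3'-most bases abut the promoter start), a net insertion trims the
    5' end.  An indel without a sufficient flank raises :class:`InputError`.
    """
    i = promoter.index_of(snp.offset)
    seq = promoter.sequence
    wt = snp.wt_allele
    if seq[i: i + len(wt)] != wt:
        raise DataError(
            f"{snp.variant_id}: reference mismatch at offset {snp.offset} of "
            f"{promoter.gene_id}: expected {wt!r}, promoter has "
            f"{seq[i: i + len(wt)]!r}"
        )
    edited = seq[:i] + snp.min_allele + seq[i + len(wt):]
    shift = len(edited) - len(seq)
    if shift < 0:  # net deletion: pad upstream from the flank
        need = -shift
        if flank_5prime is None or len(flank_5prime) < need:
            raise InputError(
                f"{snp.variant_id}: deletion needs {need} bp of upstream flank"
            )
        edited = normalize_sequence(flank_5prime)[-need:] + edited
    elif shift > 0:  # net insertion: trim the upstream end
        edited = edited[shift:]
    return PromoterRecord(
        gene_id=promoter.gene_id,
        transcript_id=promoter.transcript_id,
        sequence=edited,
        start_offset=promoter.start_offset,
    )


def z_score(wt: AffinityEstimate, mn: AffinityEstimate) -> float:
    """Fisher Z-score between the two allele estimates."""
    if wt.delta < 0 or mn.delta < 0:
        raise InputError("negative delta")
    num = abs(wt.neg_log_kd - mn.neg_log_kd)
    den2 = wt.delta**2 + mn.delta**2
    if den2 == 0.0:
        if num == 0.0:
            return 0.0
        raise DataError(
            "both deltas are zero but the estimates differ; Z is undefined"
        )
    return num / den2**0.5


def significance(z: float) -> tuple[float, float]:
    """Two-tailed standard-normal p-value of ``z`` and α = 1 − p."""
    if z < 0:
        raise InputError("z must be non-negative")
    p = float(min(1.0, 2.0 * norm.sf(z)))
    return p, 1.0 - p


def classify_expression(
    wt: AffinityEstimate,
    mn: AffinityEstimate,
    alpha: float,
    threshold: float = 0.95,
) -> Decision:
    """Map a significant affinity change to an expression direction.

    An affinity increase of the minor allele (tighter TBP binding) is read
    as overexpression, a decrease as underexpression; below-threshold α is
    insignificant.
    """
    if not 0.0 < threshold < 1.0:
        raise InputError("threshold must be in (0,1)")
    if alpha < threshold or mn.neg_log_kd == wt.neg_log_kd:
        return Decision.INSIGNIFICANT
    if mn.neg_log_kd > wt.neg_log_kd:
        return Decision.OVEREXPRESSION
    return Decision.UNDEREXPRESSION


def assign_rank(alpha: float) -> str:
    """Heuristic prediction rank ρ from A (best) to E (worst)."""
    if not 0.0 <= alpha <= 1.0:
        raise InputError(f"alpha {alpha} outside [0,1]")
    for rank, lower in RANK_BINS:
        if alpha >= lower:
            return rank
    return "E"


def compare_snp(
    promoter: PromoterRecord,
    snp: SnpRecord,
    config: ModelConfig,
    wt_estimate: AffinityEstimate | None = None,
    flank_5prime: str | None = None,
) -> ComparisonResult:
    """Full allele comparison for one SNP.

    ``wt_estimate`` may be supplied to avoid recomputing the ancestral
    allele when many SNPs share a promoter.
    """
    if wt_estimate is None:
        wt_estimate = estimate_affinity(promoter, config)
    minor = apply_variant(promoter, snp, flank_5prime=flank_5prime)
    mn_estimate = estimate_affinity(minor, config)
    z = z_score(wt_estimate, mn_estimate)
    p, alpha = significance(z)
    decision = classify_expression(
        wt_estimate, mn_estimate, alpha, config.significance_alpha_threshold
    )
    return ComparisonResult(
        variant_id=snp.variant_id,
        gene_id=snp.gene_id,
        wt=wt_estimate,
        mn=mn_estimate,
        z=z,
        p_value=p,
        alpha=alpha,
        decision=decision,
        rank=assign_rank(alpha),
    )
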
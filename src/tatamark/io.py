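"""Readers and writers for the pipeline's tabular and FASTA formats.

TSV is the primary tabular dialect; every writer emits a fixed column
order that the module's own readers re-parse.  Promoter FASTA records use
``gene_id|transcript_id`` as the record id and carry the TSS-relative
start offset in the description (``offset=-70``).  A minimal VCF dialect
is accepted as input convenience for variants (never emitted).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .affinity import ModelConfig, PromoterRecord
from .contests import ContestRecord, CrossTable, Observation
from .errors import DataError, ParseError
from .markers import DichotomyCounts, GeneAnnotation, Polarity
from .stats import TestResult
from .variants import ComparisonResult, SnpRecord

read_model_config = ModelConfig.from_yaml


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file")
        return pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=str(path))
    return df


# -- promoters ------------------------------------------------------------


def read_promoters(path: str | Path, lenient: bool = False) -> list[PromoterRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, _, transcript_id = rec.id.partition("|")
        offset = -len(rec.seq)
        for token in rec.description.split():
            if token.startswith("offset="):
                offset = int(token.split("=", 1)[1])
        records.append(
            PromoterRecord(
                gene_id=gene_id,
                transcript_id=transcript_id or gene_id,
                sequence=str(rec.seq),
                start_offset=offset,
            )
        )
    if not records:
        warnings.warn(f"{path}: no FASTA records")
    return records


def write_promoters(records: list[PromoterRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.gene_id}|{r.transcript_id}",
            description=f"offset={r.start_offset}",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# -- SNP tables -----------------------------------------------------------

SNP_COLUMNS = ["variant_id", "gene_id", "offset", "wt_allele", "min_allele"]


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    df = _read_tsv(path, SNP_COLUMNS)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                SnpRecord(
                    variant_id=row["variant_id"],
                    gene_id=row["gene_id"],
                    offset=int(row["offset"]),
                    wt_allele=row["wt_allele"],
                    min_allele=row["min_allele"],
                )
            )
        except (ValueError, TypeError) as e:
            raise ParseError(str(e), path=str(path), line=idx + 2) from e
    return records


def write_snp_table(
    records: list[SnpRecord] | list[tuple[SnpRecord, str]], path: str | Path
) -> None:
    rows = []
    for item in records:
        rec, cls = item if isinstance(item, tuple) else (item, None)
        row = {
            "variant_id": rec.variant_id,
            "gene_id": rec.gene_id,
            "offset": rec.offset,
            "wt_allele": rec.wt_allele,
            "min_allele": rec.min_allele,
        }
        if cls is not None:
            row["snp_class"] = cls
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, tss_table: str | Path) -> list[SnpRecord]:
    """Minimal VCF reader: CHROM/POS mapped to TSS-relative offsets.

    ``tss_table`` is a TSV with columns gene_id, chrom, tss, strand; the
    offset is POS − TSS on the + strand and TSS − POS on the − strand
    (with alleles reverse-complemented).  Rows mapping into no gene's
    [−70, −1] window are skipped with a warning.
    """
    tss = _read_tsv(tss_table, ["gene_id", "chrom", "tss", "strand"])
    genes = [
        (r["gene_id"], r["chrom"], int(r["tss"]), r["strand"])
        for _, r in tss.iterrows()
    ]
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError("fewer than 5 VCF fields", str(path), lineno)
            chrom, pos, vid, ref, alt = fields[:5]
            pos = int(pos)
            placed = False
            for gene_id, gchrom, gtss, strand in genes:
                if chrom != gchrom:
                    continue
                if strand == "-":
                    offset = gtss - pos
                    wt = str(Seq(ref).reverse_complement())
                    mn = str(Seq(alt).reverse_complement())
                else:
                    offset = pos - gtss
                    wt, mn = ref, alt
                if -70 <= offset <= -1:
                    records.append(
                        SnpRecord(
                            variant_id=vid if vid != "." else f"{chrom}:{pos}",
                            gene_id=gene_id,
                            offset=offset,
                            wt_allele=wt,
                            min_allele=mn,
                        )
                    )
                    placed = True
                    break
            if not placed:
                warnings.warn(f"{path}:{lineno}: variant outside all promoters")
    return records


# -- annotations ----------------------------------------------------------

ANNOTATION_COLUMNS = ["gene_id", "system", "polarity", "evidence"]


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    df = _read_tsv(path, ANNOTATION_COLUMNS[:3])
    seen: set[str] = set()
    out = []
    for idx, row in df.iterrows():
        if row["gene_id"] in seen:
            raise ParseError(
                f"duplicate gene {row['gene_id']}", str(path), idx + 2
            )
        seen.add(row["gene_id"])
        try:
            out.append(
                GeneAnnotation(
                    gene_id=row["gene_id"],
                    system=row["system"],
                    polarity=Polarity(row["polarity"]),
                    evidence=row.get("evidence", "") or "",
                )
            )
        except ValueError as e:
            raise ParseError(str(e), str(path), idx + 2) from e
    return out


def write_annotations(annotations: list[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "system": a.system,
                "polarity": a.polarity.value,
                "evidence": a.evidence,
            }
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)


# -- contests -------------------------------------------------------------

CONTEST_COLUMNS = [
    "pair_id", "maternal_strain", "paternal", "side",
    "observation_index", "attacks", "submissive_poses",
]


def read_contests(path: str | Path) -> list[ContestRecord]:
    df = _read_tsv(path, CONTEST_COLUMNS)
    if df.empty:
        return []
    records = []
    for pair_id, grp in df.groupby("pair_id", sort=False):
        sides = {}
        for side, sgrp in grp.groupby("side"):
            sgrp = sgrp.copy()
            sgrp["observation_index"] = sgrp["observation_index"].astype(int)
            sgrp = sgrp.sort_values("observation_index")
            sides[side] = sgrp
        if set(sides) != {"a", "b"}:
            raise DataError(f"{pair_id}: need observations for both sides a and b")
        a, b = sides["a"], sides["b"]
        if list(a["observation_index"]) != list(b["observation_index"]):
            raise DataError(f"{pair_id}: observation indices differ between sides")
        obs = tuple(
            Observation(
                attacks_a=int(ra["attacks"]),
                attacks_b=int(rb["attacks"]),
                submissive_a=int(ra["submissive_poses"]),
                submissive_b=int(rb["submissive_poses"]),
            )
            for (_, ra), (_, rb) in zip(a.iterrows(), b.iterrows())
        )
        records.append(
            ContestRecord(
                pair_id=pair_id,
                maternal_strain=a["maternal_strain"].iloc[0],
                male_a_paternal=a["paternal"].iloc[0],
                male_b_paternal=b["paternal"].iloc[0],
                observations=obs,
            )
        )
    return records


def write_contests(records: list[ContestRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for i, o in enumerate(rec.observations):
            for side, paternal, atk, sub in (
                ("a", rec.male_a_paternal, o.attacks_a, o.submissive_a),
                ("b", rec.male_b_paternal, o.attacks_b, o.submissive_b),
            ):
                rows.append(
                    {
                        "pair_id": rec.pair_id,
                        "maternal_strain": rec.maternal_strain,
                        "paternal": paternal,
                        "side": side,
                        "observation_index": i,
                        "attacks": atk,
                        "submissive_poses": sub,
                    }
                )
    pd.DataFrame(rows, columns=CONTEST_COLUMNS).to_csv(path, sep="\t", index=False)


# -- result tables --------------------------------------------------------

COMPARISON_COLUMNS = [
    "variant_id", "gene_id", "neg_log_kd_wt", "delta_wt", "kd_wt",
    "neg_log_kd_min", "delta_min", "kd_min", "best_window_offset_wt",
    "best_window_offset_min", "z", "p_value", "alpha", "decision", "rank",
]


def write_comparisons(results: list[ComparisonResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "gene_id": r.gene_id,
                "neg_log_kd_wt": r.wt.neg_log_kd,
                "delta_wt": r.wt.delta,
                "kd_wt": r.wt.kd,
                "neg_log_kd_min": r.mn.neg_log_kd,
                "delta_min": r.mn.delta,
                "kd_min": r.mn.kd,
                "best_window_offset_wt": r.wt.best_window_offset,
                "best_window_offset_min": r.mn.best_window_offset,
                "z": r.z,
                "p_value": r.p_value,
                "alpha": r.alpha,
                "decision": r.decision.value,
                "rank": r.rank,
            }
            for r in results
        ],
        columns=COMPARISON_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_dichotomy_table(
    counts: dict[str, DichotomyCounts],
    tests: dict[str, dict[str, TestResult]] | None = None,
    path: str | Path = "dichotomy.tsv",
) -> None:
    """One row per body system plus TOTAL, with optional test p-values."""
    rows = []
    for label, c in counts.items():
        row = {
            "system": label,
            "n_res": c.n_res,
            "n_dom": c.n_dom,
            "n_sub": c.n_sub,
            "n_over": c.n_over,
            "n_under": c.n_under,
        }
        if tests and label in tests:
            for name, t in tests[label].items():
                row[f"p_{name}"] = t.p_value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cross_table(table: CrossTable, path: str | Path) -> None:
    p1, p2 = table.paternal_strains
    rows = []
    for row in list(table.rows.values()) + [table.total]:
        rows.append(
            {
                "maternal_strain": row.maternal_strain,
                f"dominant_{p1}": row.n_dominant[p1],
                f"dominant_{p2}": row.n_dominant[p2],
                "chi2": row.test.statistic,
                "p_value": row.test.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
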
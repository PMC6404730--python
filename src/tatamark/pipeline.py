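"""The umbrella pipeline: inputs → comparisons → markers → statistics.

Mirrors the full study workflow: score both alleles of every promoter SNP,
classify expression shifts, apply the decision-making rule against the
gene annotations, tally the dichotomies with their binomial tests, and —
when contest records are supplied — build the dominance-inheritance cross
table with its χ² analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .affinity import ModelConfig, estimate_affinity
from .contests import CrossTable, tabulate_crosses
from .errors import DataError
from .io import (
    read_annotations,
    read_contests,
    read_promoters,
    read_snp_table,
    write_comparisons,
    write_cross_table,
    write_dichotomy_table,
)
from .markers import DichotomyCounts, tally
from .stats import TestResult, binom_equal_test, binom_neutral_test
from .variants import ComparisonResult, compare_snp

log = logging.getLogger("tatamark")


@dataclass
class PipelineConfig:
    fasta: str | Path
    snps: str | Path
    annotations: str | Path
    outdir: str | Path
    contests: str | Path | None = None
    model_config: str | Path | None = None
    contest_rule: str = "attacks_and_poses"

    def load_model(self) -> ModelConfig:
        if self.model_config is None:
            return ModelConfig.default()
        return ModelConfig.from_yaml(self.model_config)


def compare_all(
    promoters, snps, config: ModelConfig
) -> list[ComparisonResult]:
    """Run the allele comparison for every SNP, caching per-gene wt estimates."""
    by_gene = {p.gene_id: p for p in promoters}
    wt_cache = {}
    results = []
    for snp in snps:
        promoter = by_gene.get(snp.gene_id)
        if promoter is None:
            raise DataError(f"{snp.variant_id}: no promoter for gene {snp.gene_id}")
        if snp.gene_id not in wt_cache:
            wt_cache[snp.gene_id] = estimate_affinity(promoter, config)
        results.append(
            compare_snp(promoter, snp, config, wt_estimate=wt_cache[snp.gene_id])
        )
    return results


def dichotomy_tests(
    counts: dict[str, DichotomyCounts]
) -> dict[str, dict[str, TestResult]]:
    """Equal-split and neutral-drift tests for every non-empty tally row."""
    tests: dict[str, dict[str, TestResult]] = {}
    for label, c in counts.items():
        if c.n_res == 0:
            continue
        tests[label] = {
            "equal_dom_sub": binom_equal_test(c.n_dom, c.n_sub),
            "equal_over_under": binom_equal_test(c.n_over, c.n_under),
            "neutral_over_under": binom_neutral_test(c.n_over, c.n_under),
        }
    return tests


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Writes comparisons.tsv, dichotomy.tsv, cross.tsv (if contests given)
    and summary.json under ``config.outdir``; returns the summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = config.load_model()

    promoters = read_promoters(config.fasta)
    snps = read_snp_table(config.snps)
    annotations = {a.gene_id: a for a in read_annotations(config.annotations)}
    log.info(
        "loaded %d promoters, %d SNPs, %d annotations",
        len(promoters), len(snps), len(annotations),
    )

    results = compare_all(promoters, snps, model)
    write_comparisons(results, outdir / "comparisons.tsv")

    counts = tally((r, annotations.get(r.gene_id)) for r in results)
    tests = dichotomy_tests(counts)
    write_dichotomy_table(counts, tests, outdir / "dichotomy.tsv")

    summary: dict = {
        "n_promoters": len(promoters),
        "n_snps": len(snps),
        "dichotomy": {
            label: {
                "n_res": c.n_res,
                "n_dom": c.n_dom,
                "n_sub": c.n_sub,
                "n_over": c.n_over,
                "n_under": c.n_under,
                **{
                    f"p_{name}": t.p_value
                    for name, t in tests.get(label, {}).items()
                },
            }
            for label, c in counts.items()
        },
    }

    if config.contests is not None:
        contests = read_contests(config.contests)
        cross: CrossTable = tabulate_crosses(contests, rule=config.contest_rule)
        write_cross_table(cross, outdir / "cross.tsv")
        p1, p2 = cross.paternal_strains
        summary["cross"] = {
            "paternal_strains": [p1, p2],
            "rows": {
                row.maternal_strain: {
                    "counts": [row.n_dominant[p1], row.n_dominant[p2]],
                    "chi2": row.test.statistic,
                    "p_value": row.test.p_value,
                }
                for row in list(cross.rows.values()) + [cross.total]
            },
            "unresolved": cross.unresolved,
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir / "summary.json")
    return summary
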
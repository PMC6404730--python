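"""Synthetic-data generator: determinism, construction guarantees, recovery."""

import numpy as np
import pytest
from scipy.stats import binom

from tatamark import (
    ConfigError,
    Decision,
    Outcome,
    SimSpec,
    apply_variant,
    compare_snp,
    gen_annotations,
    gen_contests,
    gen_promoters,
    gen_variants,
    pwm_score,
    score_contest,
    tabulate_crosses,
)
from tatamark.io import write_promoters
from tatamark.markers import Polarity
from tatamark.stats import binom_equal_test


class TestPromoters:
    def test_motif_fraction_one_embeds_consensus_everywhere(self, default_config):
        spec = SimSpec(seed=5, n_genes=30, motif_fraction=1.0,
                       damaged_motif_fraction=0.0)
        cons = default_config.consensus()
        for rec in gen_promoters(spec, default_config):
            assert cons in rec.sequence
            assert len(rec.sequence) == 70
            assert rec.start_offset == -70

    def test_same_seed_gives_identical_fasta_bytes(self, default_config, tmp_path):
        paths = []
        for i in (1, 2):
            recs = gen_promoters(SimSpec(seed=42, n_genes=20), default_config)
            p = tmp_path / f"run{i}.fasta"
            write_promoters(recs, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_embedded_motif_count_within_binomial_bounds(self, default_config):
        spec = SimSpec(seed=9, n_genes=200, motif_fraction=0.5,
                       damaged_motif_fraction=0.0)
        cons = default_config.consensus()
        count = sum(cons in r.sequence
                    for r in gen_promoters(spec, default_config))
        lo, hi = binom.ppf([0.005, 0.995], 200, 0.5)
        assert lo <= count <= hi


@pytest.fixture(scope="module")
def study(default_config):
    spec = SimSpec(seed=13, n_genes=60, mean_snps_per_gene=6.0,
                   motif_fraction=0.35, damaged_motif_fraction=0.25,
                   effect_mix=(0.3, 0.3, 0.4))
    promoters = gen_promoters(spec, default_config)
    variants = gen_variants(promoters, spec, default_config)
    return promoters, variants


class TestVariants:
    def test_wt_allele_always_matches_sequence(self, study):
        promoters, variants = study
        by_gene = {p.gene_id: p for p in promoters}
        for snp, _ in variants:
            p = by_gene[snp.gene_id]
            i = p.index_of(snp.offset)
            assert p.sequence[i] == snp.wt_allele

    def test_disrupting_snps_lower_the_motif_window_pwm_score(
        self, study, default_config
    ):
        promoters, variants = study
        by_gene = {p.gene_id: p for p in promoters}
        cons = default_config.consensus()
        w = default_config.window_length
        checked = 0
        for snp, cls in variants:
            if cls != "disrupting":
                continue
            p = by_gene[snp.gene_id]
            site = p.sequence.find(cons)
            assert site >= 0
            mutated = apply_variant(p, snp)
            before = pwm_score(p.sequence[site: site + w], default_config.pwm)
            after = pwm_score(mutated.sequence[site: site + w],
                              default_config.pwm)
            assert after < before
            checked += 1
        assert checked > 0

    def test_background_snps_avoid_the_motif_window(self, study, default_config):
        promoters, variants = study
        by_gene = {p.gene_id: p for p in promoters}
        cons = default_config.consensus()
        w = default_config.window_length
        for snp, cls in variants:
            if cls != "background":
                continue
            p = by_gene[snp.gene_id]
            site = p.sequence.find(cons)
            if site >= 0:
                i = p.index_of(snp.offset)
                assert not site <= i < site + w

    def test_class_counts_reproducible_for_fixed_seed(self, study,
                                                      default_config):
        promoters, variants = study
        spec = SimSpec(seed=13, n_genes=60, mean_snps_per_gene=6.0,
                       motif_fraction=0.35, damaged_motif_fraction=0.25,
                       effect_mix=(0.3, 0.3, 0.4))
        again = gen_variants(promoters, spec, default_config)
        assert [(s.variant_id, s.offset, s.wt_allele, s.min_allele, c)
                for s, c in variants] == [
            (s.variant_id, s.offset, s.wt_allele, s.min_allele, c)
            for s, c in again
        ]

    def test_motif_targeted_snps_without_motifs_is_a_config_error(
        self, default_config
    ):
        spec = SimSpec(seed=1, n_genes=5, motif_fraction=0.0,
                       damaged_motif_fraction=0.0, effect_mix=(0.5, 0.0, 0.5))
        promoters = gen_promoters(spec, default_config)
        with pytest.raises(ConfigError):
            gen_variants(promoters, spec, default_config)


class TestAnnotationsAndContests:
    def test_polarity_mix_extremes(self):
        spec = SimSpec(seed=3, n_genes=40, polarity_mix=1.0)
        anns = gen_annotations(spec)
        assert all(a.polarity is Polarity.EXCESS_MARKS_DOMINANCE for a in anns)

    def test_p_dom_one_gives_unanimous_cross_table(self):
        spec = SimSpec(seed=4, p_dom=1.0)
        table = tabulate_crosses(gen_contests(spec))
        assert table.counts("TOTAL") == (115, 0)
        assert not table.unresolved

    def test_scoring_recovers_every_drawn_winner(self):
        # p_dom=0 makes every CBA/cLac-sired male the intended winner, so
        # scoring must yield (0, 115) with no unresolved pairs
        spec = SimSpec(seed=6, p_dom=0.0)
        contests = gen_contests(spec)
        assert all(score_contest(r) is not Outcome.UNRESOLVED for r in contests)
        table = tabulate_crosses(contests)
        assert table.counts("TOTAL") == (0, 115)

    def test_design_pair_counts(self):
        spec = SimSpec(seed=8)
        contests = gen_contests(spec)
        per_strain = {}
        for r in contests:
            per_strain[r.maternal_strain] = per_strain.get(r.maternal_strain, 0) + 1
        assert per_strain == {"PT": 31, "C57BL/6J": 20, "YT": 21,
                              "DD": 20, "A/He": 23}

    def test_observed_dominance_rate_parameterisation(self):
        # at p_dom = 79/115 the mean simulated BALB-dominant total over
        # replicate studies sits near 79 of 115
        totals = []
        for seed in range(30):
            spec = SimSpec(seed=1000 + seed)
            totals.append(tabulate_crosses(gen_contests(spec)).counts("TOTAL")[0])
        mean = np.mean(totals)
        # 3 sigma of a Bernoulli(79/115) mean over 30*115 draws
        sd = np.sqrt(115 * (79 / 115) * (36 / 115) / 30)
        assert abs(mean - 79) < 3 * sd


class TestEndToEndRecovery:
    def test_effect_direction_recovered_far_above_background(
        self, default_config
    ):
        """Motif-disrupting SNPs are called underexpression and creating
        SNPs overexpression at rates far above background SNPs."""
        spec = SimSpec(seed=21, n_genes=120, mean_snps_per_gene=5.0,
                       motif_fraction=0.4, damaged_motif_fraction=0.3,
                       effect_mix=(0.4, 0.4, 0.2))
        promoters = gen_promoters(spec, default_config)
        variants = gen_variants(promoters, spec, default_config)
        by_gene = {p.gene_id: p for p in promoters}
        hits = {"disrupting": [0, 0], "creating": [0, 0], "background": [0, 0]}
        for snp, cls in variants:
            res = compare_snp(by_gene[snp.gene_id], snp, default_config)
            hits[cls][1] += 1
            want = {"disrupting": Decision.UNDEREXPRESSION,
                    "creating": Decision.OVEREXPRESSION}.get(cls)
            if want is not None and res.decision is want:
                hits[cls][0] += 1
            elif want is None and res.decision is not Decision.INSIGNIFICANT:
                hits[cls][0] += 1
        n_total = sum(v[1] for v in hits.values())
        assert n_total >= 500
        rate = {k: v[0] / v[1] for k, v in hits.items()}
        assert rate["disrupting"] > 0.5
        assert rate["creating"] > 0.5
        assert rate["background"] < 0.1
        assert rate["disrupting"] > 5 * rate["background"]
        assert rate["creating"] > 5 * rate["background"]

    def test_balanced_polarity_gives_balanced_marker_split(self, default_config):
        """With a 50:50 polarity mix the dominance/subordination tally is
        statistically balanced in nearly all replicate studies.

        Polarity is a gene-level attribute, so genes carrying several
        significant SNPs contribute correlated marker calls; the binomial
        reference for the split applies in the low-density regime of about
        one SNP per gene, which is the condition simulated here.
        """
        from tatamark.markers import tally

        passed = 0
        n_rep = 30
        for seed in range(n_rep):
            spec = SimSpec(seed=3000 + seed, n_genes=150, mean_snps_per_gene=1.0,
                           motif_fraction=0.4, damaged_motif_fraction=0.3,
                           effect_mix=(0.4, 0.4, 0.2), polarity_mix=0.5)
            promoters = gen_promoters(spec, default_config)
            variants = gen_variants(promoters, spec, default_config)
            anns = {a.gene_id: a
                    for a in gen_annotations(spec, [p.gene_id for p in promoters])}
            by_gene = {p.gene_id: p for p in promoters}
            results = [compare_snp(by_gene[s.gene_id], s, default_config)
                       for s, _ in variants]
            counts = tally((r, anns.get(r.gene_id)) for r in results)
            total = counts["TOTAL"]
            if total.n_res == 0:
                continue
            if binom_equal_test(total.n_dom, total.n_sub).p_value > 0.05:
                passed += 1
        assert passed >= 0.9 * n_rep
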
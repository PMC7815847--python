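"""The generator must plant exactly what downstream stages are scored against:
consistent categories, usage fractions, read layout and coverage drops."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ipaseq import SimConfig, build_toy_world
from ipaseq.genome import revcomp
from ipaseq.synthetic_data import (
    DECOY_A_RUN,
    SimParameterError,
    TruthSet,
    TruthSite,
    UnknownConditionError,
    read_origin,
    simulate_rnaseq_library,
    simulate_threads_library,
)


def test_empty_world():
    genome, models, truth = build_toy_world(SimConfig(n_genes=0))
    assert models == [] and truth.sites == [] and truth.decoys == []


def test_world_deterministic(small_config):
    g1, m1, t1 = build_toy_world(small_config)
    g2, m2, t2 = build_toy_world(small_config)
    assert g1.sequences == g2.sequences
    assert m1 == m2
    assert t1.sites == t2.sites and t1.decoys == t2.decoys


def test_fastq_deterministic(small_world):
    cfg, genome, _models, truth = small_world
    r1 = simulate_threads_library(genome, truth, "UD", cfg, 1)
    r2 = simulate_threads_library(genome, truth, "UD", cfg, 1)
    assert r1 == r2


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_genes", -1),
        ("reads_per_library", -5),
        ("insert_length", 10),
        ("non_t_error_prob", 1.5),
        ("internal_priming_fraction", -0.1),
        ("tail_length_distribution", {1: 1.0}),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = SimConfig(**{field: value})
    with pytest.raises(SimParameterError, match=field):
        cfg.validate()


def test_usage_fractions_sum_to_one(small_world):
    _cfg, _genome, _models, truth = small_world
    for gene in {s.gene_id for s in truth.sites}:
        for cond in truth.conditions():
            total = sum(
                s.usage_fraction_by_condition[cond] for s in truth.sites_of(gene)
            )
            assert total == pytest.approx(1.0, abs=1e-9)


def test_truth_categories_match_interval_membership(small_world):
    """Brute-force re-derivation of each site's category from the emitted
    gene models must equal the stored category."""
    _cfg, _genome, models, truth = small_world
    by_gene = {m.gene_id: m for m in models}
    for site in truth.sites:
        m = by_gene[site.gene_id]
        p = site.cleavage_pos
        in_intron = any(s <= p < e for s, e in m.introns)
        in_utr3 = any(s <= p < e for s, e in m.utr3)
        expected = "intron" if in_intron else ("utr3" if in_utr3 else "exon")
        assert expected == site.category, (site.gene_id, p)


def test_hexamer_planted_upstream_of_every_site(small_world):
    _cfg, genome, _models, truth = small_world
    for site in truth.sites:
        p = site.cleavage_pos
        if site.strand == "+":
            upstream = genome.fetch_sense(site.chrom, p - 40, p + 1, "+")
        else:
            upstream = genome.fetch_sense(site.chrom, p, p + 41, "-")
        assert "AATAAA" in upstream


def test_decoys_sit_upstream_of_genomic_a_runs(small_world):
    _cfg, genome, _models, truth = small_world
    assert truth.decoys
    for chrom, strand, pos in truth.decoys:
        if strand == "+":
            run = genome.fetch_sense(chrom, pos + 1, pos + 1 + DECOY_A_RUN, "+")
        else:
            run = genome.fetch_sense(chrom, pos - DECOY_A_RUN, pos, "-")
        assert run == "A" * DECOY_A_RUN


def test_zero_reads_gives_empty_library(small_world):
    cfg, genome, _models, truth = small_world
    cfg0 = SimConfig(**{**vars(cfg), "reads_per_library": 0})
    assert simulate_threads_library(genome, truth, "UD", cfg0, 1) == []


def test_unknown_condition_raises(small_world):
    cfg, genome, _models, truth = small_world
    with pytest.raises(UnknownConditionError):
        simulate_threads_library(genome, truth, "nope", cfg, 1)


def test_clean_reads_follow_documented_layout(small_world):
    """With no tail errors and no decoys, every read is
    UMI + T-run + revcomp(transcript 3' end at a truth site)."""
    cfg, genome, _models, truth = small_world
    clean = SimConfig(
        **{
            **vars(cfg),
            "non_t_error_prob": 0.0,
            "internal_priming_fraction": 0.0,
            "reads_per_library": 500,
        }
    )
    truth_pos = {(s.chrom, s.cleavage_pos): s for s in truth.sites}
    for rec in simulate_threads_library(genome, truth, "UD", clean, 1):
        kind, _gene, chrom, pos = read_origin(rec.read_id)
        assert kind == "site"
        site = truth_pos[(chrom, pos)]
        body = rec.sequence[clean.umi_length :]
        tail_len = len(body) - len(body.lstrip("T"))
        insert = body[tail_len:]
        if site.strand == "+":
            expected = revcomp(genome.fetch(chrom, pos - clean.insert_length + 1, pos + 1))
        else:
            expected = genome.fetch(chrom, pos, pos + clean.insert_length)
        # leading T's of the true insert are absorbed into the observed tail
        assert expected.endswith(insert)
        absorbed = len(expected) - len(insert)
        assert set(expected[:absorbed]) <= {"T"}
        assert 8 <= tail_len - absorbed <= 20


def test_read_shares_match_planted_usage(small_world):
    """Observed per-site read shares within each gene stay within 3 binomial
    standard deviations of the planted usage for >=95% of sites."""
    cfg, genome, _models, truth = small_world
    big = SimConfig(
        **{**vars(cfg), "reads_per_library": 50_000, "internal_priming_fraction": 0.0}
    )
    recs = simulate_threads_library(genome, truth, "UD", big, 1)
    counts: dict[tuple[str, int], int] = {}
    for rec in recs:
        _kind, _gene, chrom, pos = read_origin(rec.read_id)
        counts[(chrom, pos)] = counts.get((chrom, pos), 0) + 1
    gene_totals: dict[str, int] = {}
    for site in truth.sites:
        gene_totals[site.gene_id] = gene_totals.get(site.gene_id, 0) + counts.get(
            (site.chrom, site.cleavage_pos), 0
        )
    ok = total = 0
    for site in truth.sites:
        n = gene_totals[site.gene_id]
        if n < 50:
            continue
        u = site.usage_fraction_by_condition["UD"]
        observed = counts.get((site.chrom, site.cleavage_pos), 0) / n
        sd = np.sqrt(max(u * (1 - u), 1e-12) / n)
        total += 1
        ok += abs(observed - u) <= 3 * sd + 1e-12
    assert total > 20
    assert ok / total >= 0.95


# --- RNA-seq ---------------------------------------------------------------


def _single_gene_world(usage_ipa: float):
    cfg = SimConfig(n_genes=1, seed=3, ipa_gene_fraction=1.0, differential_fraction=0.0)
    genome, models, truth = build_toy_world(cfg)
    sites = [
        TruthSite(
            gene_id=s.gene_id,
            chrom=s.chrom,
            strand=s.strand,
            cleavage_pos=s.cleavage_pos,
            category=s.category,
            usage_fraction_by_condition={
                "UD": usage_ipa if s.category == "intron" else 1.0 - usage_ipa
            },
        )
        for s in truth.sites
    ]
    truth = TruthSet(
        sites=sites,
        decoys=truth.decoys,
        gene_expression_by_condition={"UD": {"g0000": 1.0}},
    )
    return genome, models, truth


def test_rnaseq_zero_reads_empty():
    genome, models, truth = _single_gene_world(0.5)
    table = simulate_rnaseq_library(genome, models, truth, "UD", 0, seed=1)
    assert len(table) == 0


def test_rnaseq_full_ipa_usage_leaves_downstream_empty():
    """A gene whose IpA usage is 1.0 yields no reads downstream of the site."""
    genome, models, truth = _single_gene_world(1.0)
    ipa = next(s for s in truth.sites if s.category == "intron")
    table = simulate_rnaseq_library(genome, models, truth, "UD", 20_000, seed=2)
    if ipa.strand == "+":
        downstream = table[table["start"] > ipa.cleavage_pos]
    else:
        downstream = table[table["end"] <= ipa.cleavage_pos]
    assert len(downstream) == 0


def test_rnaseq_window_ratio_matches_analytic_expectation():
    """Upstream:downstream coverage at a 50%-used IpA site equals
    (u(1-rho)+rho)/rho; with pre-mRNA fraction 1/3 that is exactly 2.0."""
    genome, models, truth = _single_gene_world(0.5)
    ipa = next(s for s in truth.sites if s.category == "intron")
    table = simulate_rnaseq_library(
        genome, models, truth, "UD", 100_000, seed=4, pre_mrna_fraction=1.0 / 3.0
    )
    p = ipa.cleavage_pos
    if ipa.strand == "+":
        up = ((table["start"] < p + 1) & (table["end"] > p - 99)).sum()
        down = ((table["start"] < p + 101) & (table["end"] > p + 1)).sum()
    else:
        up = ((table["start"] < p + 100) & (table["end"] > p)).sum()
        down = ((table["start"] < p) & (table["end"] > p - 100)).sum()
    assert down > 100
    assert up / down == pytest.approx(2.0, rel=0.15)


def test_rnaseq_counts_track_planted_abundance():
    """Two structurally identical genes with 2:1 abundance give ~2:1 reads."""
    cfg = SimConfig(n_genes=1, seed=9, ipa_gene_fraction=0.0, two_utr3_fraction=0.0)
    genome, models, truth = build_toy_world(cfg)
    m = models[0]
    shift = 10_000
    m2 = type(m)(
        gene_id="g0001",
        chrom="chr2",
        strand=m.strand,
        exons=tuple((s + shift, e + shift) for s, e in m.exons),
        utr3=tuple((s + shift, e + shift) for s, e in m.utr3),
    )
    chr1 = genome.sequences["chr1"]
    genome.sequences["chr2"] = "N" * shift + chr1
    s0 = truth.sites[0]
    sites = [
        s0,
        TruthSite("g0001", "chr2", s0.strand, s0.cleavage_pos + shift, s0.category,
                  {"UD": 1.0}),
    ]
    truth2 = TruthSet(
        sites=sites,
        decoys=[],
        gene_expression_by_condition={"UD": {"g0000": 2.0, "g0001": 1.0}},
    )
    table = simulate_rnaseq_library(genome, [m, m2], truth2, "UD", 60_000, seed=5)
    n1 = (table["chrom"] == "chr1").sum()
    n2 = (table["chrom"] == "chr2").sum()
    assert n1 / n2 == pytest.approx(2.0, rel=0.1)


def test_library_size_is_exact(small_world):
    cfg, genome, _models, truth = small_world
    recs = simulate_threads_library(genome, truth, "DF", cfg, 2)
    assert len(recs) == cfg.reads_per_library
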
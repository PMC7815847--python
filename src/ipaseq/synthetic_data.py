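"""Synthetic two-condition 3'-end-sequencing worlds with planted ground truth.

The generator emits a toy genome, single-isoform three-exon gene models, a
:class:`TruthSet` of planted cleavage sites with per-condition usage
fractions, 3'READS+-style FASTQ libraries and strand-specific RNA-seq read
positions. Every downstream stage of the pipeline is therefore testable with
no external data.

Read layout (after demultiplexing, 5' adapter already absent):

    [UMI, 4 random nt][residual T tail][reverse complement of the transcript
    3' end, ``insert_length`` bases ending at the cleavage site]

The tail base adjacent to the insert corresponds to the genomic base
immediately downstream of the cleavage site; internal-priming decoy reads
exploit this by drawing their tails entirely from planted genomic A-runs.
A canonical AATAAA hexamer is planted upstream of every true site, and the
genomic base immediately downstream of a true site is forced to be non-A so
that tail rescue never walks past the planted position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Genome, revcomp
from .site_calling import GeneModel

DECOY_A_RUN = 35        # length of planted genomic A-runs backing decoy reads
_DECOY_MAX_TAIL = 20    # decoy tails capped at the default rescue window
_BASES = np.array(list("ACGT"))


class SimParameterError(ValueError):
    """An invalid SimConfig field (the message names the field)."""


class UnknownConditionError(KeyError):
    """Requested condition absent from the truth's usage maps."""


@dataclass(frozen=True)
class TruthSite:
    gene_id: str
    chrom: str
    strand: str
    cleavage_pos: int                      # 0-based last transcribed base
    category: str                          # "intron" | "utr3"
    usage_fraction_by_condition: dict[str, float]


@dataclass(frozen=True)
class TruthSet:
    sites: list[TruthSite]
    decoys: list[tuple[str, str, int]]     # (chrom, strand, position)
    gene_expression_by_condition: dict[str, dict[str, float]]
    knockdown_responsive: frozenset[str] = frozenset()

    def conditions(self) -> list[str]:
        return sorted(self.gene_expression_by_condition)

    def sites_of(self, gene_id: str) -> list[TruthSite]:
        return [s for s in self.sites if s.gene_id == gene_id]


def default_tail_distribution() -> dict[int, float]:
    """Residual T-tail lengths: uniform over 8..20 nt."""
    lengths = range(8, 21)
    p = 1.0 / len(lengths)
    return {n: p for n in lengths}


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1200, 2000)
    replicates_per_condition: int = 2
    reads_per_library: int = 50_000
    tail_length_distribution: dict[int, float] = field(
        default_factory=default_tail_distribution
    )
    non_t_error_prob: float = 0.15
    internal_priming_fraction: float = 0.05
    umi_length: int = 4
    insert_length: int = 40
    seed: int = 0
    conditions: tuple[str, str] = ("UD", "DF")
    ipa_gene_fraction: float = 0.4         # genes carrying an intron-1 site
    differential_fraction: float = 0.5     # of IpA genes: usage shifts UD->DF
    down_fraction: float = 0.6             # of differential sites: usage drops
    two_utr3_fraction: float = 0.5         # of non-IpA genes: tandem 3'UTR sites
    distal_shift_fraction: float = 0.5     # of tandem genes: distal usage shifts
    include_knockdown: bool = False        # add CTRL/KD conditions
    knockdown_responsive_fraction: float = 0.4
    spacer_length: int = 300

    def validate(self) -> None:
        if self.n_genes < 0:
            raise SimParameterError("n_genes must be >= 0")
        lo, hi = self.gene_length_range
        if lo < 1200 or hi < lo:
            raise SimParameterError("gene_length_range must satisfy 1200 <= lo <= hi")
        if self.replicates_per_condition < 1:
            raise SimParameterError("replicates_per_condition must be >= 1")
        if self.reads_per_library < 0:
            raise SimParameterError("reads_per_library must be >= 0")
        if self.umi_length < 0:
            raise SimParameterError("umi_length must be >= 0")
        if self.insert_length < 22:
            raise SimParameterError("insert_length must be >= 22")
        if self.spacer_length < 160:
            raise SimParameterError("spacer_length must be >= 160")
        dist = self.tail_length_distribution
        if not dist or any(n < 2 or n > 30 for n in dist):
            raise SimParameterError("tail_length_distribution keys must lie in 2..30")
        if any(p < 0 for p in dist.values()) or abs(sum(dist.values()) - 1) > 1e-6:
            raise SimParameterError("tail_length_distribution must be a probability distribution")
        for name in (
            "non_t_error_prob",
            "internal_priming_fraction",
            "ipa_gene_fraction",
            "differential_fraction",
            "down_fraction",
            "two_utr3_fraction",
            "distal_shift_fraction",
            "knockdown_responsive_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimParameterError(f"{name} must be in [0, 1]")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise SimParameterError("conditions must be two distinct names")

    def all_conditions(self) -> tuple[str, ...]:
        if self.include_knockdown:
            return self.conditions + ("CTRL", "KD")
        return self.conditions


# ---------------------------------------------------------------------------
# world construction


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)].copy()


def _plant_site(seq: np.ndarray, pos: int, rng: np.random.Generator) -> None:
    """Plant AATAAA 10-40 bp upstream of ``pos`` (sense-local coordinates) and
    force the base immediately downstream to be non-A so tail rescue stops."""
    d = int(rng.integers(10, 35))               # hexamer 3' end d bp upstream
    seq[pos - d - 5 : pos - d + 1] = list("AATAAA")
    if pos + 1 < len(seq):
        seq[pos + 1] = "C"


def build_toy_world(config: SimConfig) -> tuple[Genome, list[GeneModel], TruthSet]:
    """Deterministically generate (genome, gene models, truth) from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    conditions = config.all_conditions()
    cond_a, cond_b = config.conditions

    chrom_parts: dict[str, list[str]] = {"chr1": [], "chr2": []}
    chrom_len: dict[str, int] = {"chr1": 0, "chr2": 0}
    models: list[GeneModel] = []
    sites: list[TruthSite] = []
    decoys: list[tuple[str, str, int]] = []
    knockdown_responsive: set[str] = set()

    n_decoys = max(2, config.n_genes // 10) if config.n_genes else 0
    decoy_every = max(1, config.n_genes // n_decoys) if n_decoys else 0

    for i in range(config.n_genes):
        gene_id = f"g{i:04d}"
        chrom = "chr1" if i < (config.n_genes + 1) // 2 else "chr2"
        strand = "+" if i % 2 == 0 else "-"

        # intergenic spacer, optionally carrying a decoy A-run
        spacer = _random_seq(rng, config.spacer_length)
        if n_decoys and i % decoy_every == 0 and len(decoys) < n_decoys:
            s0 = chrom_len[chrom]
            # the two bases at/before the decoy position are fixed so the
            # trimming scan never eats into the decoy insert
            if len(decoys) % 2 == 0:      # '+' decoy: A-run downstream of pos
                spacer[80 : 80 + DECOY_A_RUN] = "A"
                spacer[78], spacer[79] = "C", "G"
                decoys.append((chrom, "+", s0 + 79))
            else:                          # '-' decoy: T-run = sense A downstream
                spacer[80 : 80 + DECOY_A_RUN] = "T"
                spacer[80 + DECOY_A_RUN] = "G"
                spacer[81 + DECOY_A_RUN] = "G"
                decoys.append((chrom, "-", s0 + 80 + DECOY_A_RUN))
        chrom_parts[chrom].append("".join(spacer))
        chrom_len[chrom] += config.spacer_length

        # gene structure (sense-local): exon1 intron1 exon2 intron2 exon3
        total = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        e1 = int(total * rng.uniform(0.10, 0.16))
        e2 = int(total * rng.uniform(0.06, 0.10))
        i2 = int(total * rng.uniform(0.12, 0.18))
        i1 = max(260, int(total * rng.uniform(0.25, 0.35)))
        e3 = total - e1 - e2 - i1 - i2
        utr3 = min(max(170, int(e3 * 0.6)), e3 - 30)

        seq = _random_seq(rng, total)

        # site placement (sense-local) and usage fractions per condition
        distal = total - 15
        ipa_pos = e1 + i1 // 2
        local_sites: list[tuple[int, str, dict[str, float]]] = []
        is_ipa = rng.random() < config.ipa_gene_fraction
        if is_ipa:
            if rng.random() < config.differential_fraction:
                hi, lo = 0.6, 0.2
                if rng.random() < config.down_fraction:
                    u = {cond_a: hi, cond_b: lo}
                else:
                    u = {cond_a: lo, cond_b: hi}
                if config.include_knockdown:
                    responsive = rng.random() < config.knockdown_responsive_fraction
                    u["CTRL"] = u[cond_a]
                    u["KD"] = u[cond_b] if responsive else u[cond_a]
                    if responsive:
                        knockdown_responsive.add(gene_id)
            else:
                u = {c: 0.35 for c in conditions}
            local_sites.append((ipa_pos, "intron", u))
            local_sites.append((distal, "utr3", {c: 1.0 - u[c] for c in conditions}))
        elif rng.random() < config.two_utr3_fraction:
            proximal = distal - 120
            if rng.random() < config.distal_shift_fraction:
                if rng.random() < 0.5:
                    dfrac = {cond_a: 0.3, cond_b: 0.7}       # lengthened
                else:
                    dfrac = {cond_a: 0.7, cond_b: 0.3}       # shortened
            else:
                dfrac = {cond_a: 0.5, cond_b: 0.5}
            dfrac = {c: dfrac.get(c, dfrac[cond_a]) for c in conditions}
            local_sites.append((proximal, "utr3", {c: 1.0 - dfrac[c] for c in conditions}))
            local_sites.append((distal, "utr3", dfrac))
        else:
            local_sites.append((distal, "utr3", {c: 1.0 for c in conditions}))

        for pos, _cat, _u in local_sites:
            _plant_site(seq, pos, rng)

        g0 = chrom_len[chrom]
        segment = "".join(seq) if strand == "+" else revcomp("".join(seq))
        chrom_parts[chrom].append(segment)
        chrom_len[chrom] += total

        def gmap(s: int, e: int) -> tuple[int, int]:
            if strand == "+":
                return g0 + s, g0 + e
            return g0 + total - e, g0 + total - s

        exons_local = [(0, e1), (e1 + i1, e1 + i1 + e2), (total - e3, total)]
        model = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(gmap(s, e) for s, e in exons_local),
            utr3=(gmap(total - utr3, total),),
        )
        models.append(model)
        for pos, cat, usage in local_sites:
            gpos = g0 + pos if strand == "+" else g0 + total - 1 - pos
            sites.append(
                TruthSite(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    cleavage_pos=gpos,
                    category=cat,
                    usage_fraction_by_condition=dict(usage),
                )
            )

    # trailing spacers so rescue windows never run off a contig
    for chrom in chrom_parts:
        chrom_parts[chrom].append("".join(_random_seq(rng, config.spacer_length)))
        chrom_len[chrom] += config.spacer_length

    genome = Genome({c: "".join(parts) for c, parts in chrom_parts.items() if parts})

    weights = rng.lognormal(0.0, 0.6, config.n_genes)
    weights = weights / weights.sum() if config.n_genes else weights
    expression = {
        cond: {f"g{i:04d}": float(w) for i, w in enumerate(weights)}
        for cond in conditions
    }
    truth = TruthSet(
        sites=sites,
        decoys=decoys,
        gene_expression_by_condition=expression,
        knockdown_responsive=frozenset(knockdown_responsive),
    )
    return genome, models, truth


# ---------------------------------------------------------------------------
# 3'READS+ library simulation


@dataclass(frozen=True)
class FastqRecord:
    read_id: str
    sequence: str
    quality: str


def _site_insert(genome: Genome, chrom: str, strand: str, pos: int, n: int) -> str:
    """Read insert for a cleavage at ``pos``: reverse complement of the sense
    transcript's last ``n`` bases."""
    if strand == "+":
        return revcomp(genome.fetch(chrom, pos - n + 1, pos + 1))
    return genome.fetch(chrom, pos, pos + n)


def read_origin(read_id: str) -> tuple[str, str, str, int]:
    """Decode (kind, gene_id, chrom, position) from a simulated read id."""
    tag = read_id.split("|", 1)[1]
    kind, gene, chrom, pos, _strand = tag.split(":")
    return kind, gene, chrom, int(pos)


def simulate_threads_library(
    genome: Genome,
    truth: TruthSet,
    condition: str,
    config: SimConfig,
    replicate_index: int,
) -> list[FastqRecord]:
    """One 3'READS+ library: exactly ``reads_per_library`` records.

    Site choice is multinomial over gene expression x usage fraction; a
    fraction ``internal_priming_fraction`` of reads is generated at decoy
    positions with tails fully matching genomic downstream A's. Read ids carry
    the generating site (``|site:gene:chrom:pos:strand`` or ``|decoy:...``) so
    recovery can be scored against truth.
    """
    if condition not in truth.gene_expression_by_condition:
        raise UnknownConditionError(
            f"condition {condition!r} not in truth (have {truth.conditions()})"
        )
    conditions = truth.conditions()
    rng = np.random.default_rng(
        [config.seed % (2**31), conditions.index(condition), replicate_index, 7]
    )
    n = config.reads_per_library
    if n == 0 or not truth.sites:
        return []

    expr = truth.gene_expression_by_condition[condition]
    site_list = truth.sites
    w = np.array(
        [expr[s.gene_id] * s.usage_fraction_by_condition[condition] for s in site_list]
    )
    w = w / w.sum()
    n_decoy = int(round(n * config.internal_priming_fraction)) if truth.decoys else 0
    n_site = n - n_decoy

    tail_lens = np.array(sorted(config.tail_length_distribution))
    tail_p = np.array([config.tail_length_distribution[k] for k in tail_lens])

    inserts = {
        id(s): _site_insert(genome, s.chrom, s.strand, s.cleavage_pos, config.insert_length)
        for s in site_list
    }
    decoy_inserts = [
        _site_insert(genome, c, st, p, config.insert_length) for (c, st, p) in truth.decoys
    ]

    choices = rng.choice(len(site_list), size=n_site, p=w)
    lengths = rng.choice(tail_lens, size=n, p=tail_p)
    has_err = rng.random(n_site) < config.non_t_error_prob
    umis = _BASES[rng.integers(0, 4, (n, config.umi_length))]

    records: list[FastqRecord] = []
    for i in range(n_site):
        s = site_list[choices[i]]
        L = int(lengths[i])
        tail = ["T"] * L
        if has_err[i] and L >= 2:
            # never at the insert-adjacent terminal base (tail[-1])
            j = int(rng.integers(0, L - 1))
            tail[j] = "ACG"[int(rng.integers(0, 3))]
        seq = "".join(umis[i]) + "".join(tail) + inserts[id(s)]
        rid = (
            f"{condition}.{replicate_index}.{i:06d}"
            f"|site:{s.gene_id}:{s.chrom}:{s.cleavage_pos}:{s.strand}"
        )
        records.append(FastqRecord(rid, seq, "I" * len(seq)))
    for i in range(n_decoy):
        d = int(rng.integers(0, len(truth.decoys)))
        chrom, strand, pos = truth.decoys[d]
        # decoy tails stay within the genomic A-run and the rescue window, so
        # every decoy tail base is explained by genomic A's
        L = min(int(lengths[n_site + i]), DECOY_A_RUN, _DECOY_MAX_TAIL)
        seq = "".join(umis[n_site + i]) + "T" * L + decoy_inserts[d]
        rid = f"{condition}.{replicate_index}.d{i:06d}|decoy:NA:{chrom}:{pos}:{strand}"
        records.append(FastqRecord(rid, seq, "I" * len(seq)))
    return records


# ---------------------------------------------------------------------------
# RNA-seq simulation


def _isoform_blocks(
    model: GeneModel, site: TruthSite
) -> list[tuple[int, int]]:
    """Genomic blocks of the isoform terminating at ``site``, in transcript order."""
    tex = list(model.exons) if model.strand == "+" else list(reversed(model.exons))
    p = site.cleavage_pos
    if site.category == "intron":
        # first exon read through into the intron, ending at the cleavage site
        if model.strand == "+":
            return [(tex[0][0], p + 1)]
        return [(p, tex[0][1])]
    blocks = tex[:-1]
    if model.strand == "+":
        return blocks + [(tex[-1][0], p + 1)]
    return blocks + [(p, tex[-1][1])]


def simulate_rnaseq_library(
    genome: Genome,
    models: list[GeneModel],
    truth: TruthSet,
    condition: str,
    n_reads: int,
    seed: int,
    read_length: int = 75,
    pre_mrna_fraction: float = 0.0,
) -> pd.DataFrame:
    """Strand-specific single-end RNA-seq positions as (chrom, strand, start, end).

    Reads are drawn uniformly along spliced isoforms whose molecule weights
    are gene expression x site usage (times transcript length, as read counts
    are in real sequencing); an isoform ending at an intronic site retains
    intron sequence up to its cleavage position, so coverage drops sharply
    after a used IpA site. ``pre_mrna_fraction`` of each gene's reads instead
    derive from the unspliced pre-mRNA spanning the whole gene. Reads are
    truncated at block (exon/isoform) boundaries, never crossing junctions.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if condition not in truth.gene_expression_by_condition:
        raise UnknownConditionError(f"condition {condition!r} not in truth")
    cols = ["chrom", "strand", "start", "end"]
    if n_reads == 0 or not truth.sites:
        return pd.DataFrame(columns=cols)

    rng = np.random.default_rng([seed % (2**31), 11])
    expr = truth.gene_expression_by_condition[condition]
    by_gene = {m.gene_id: m for m in models}

    blocks_list: list[list[tuple[int, int]]] = []
    strands: list[str] = []
    chroms: list[str] = []
    weights: list[float] = []
    for site in truth.sites:
        model = by_gene[site.gene_id]
        u = site.usage_fraction_by_condition[condition]
        if u <= 0:
            continue
        blocks_list.append(_isoform_blocks(model, site))
        strands.append(model.strand)
        chroms.append(model.chrom)
        weights.append(expr[site.gene_id] * u * (1.0 - pre_mrna_fraction))
    if pre_mrna_fraction > 0:
        for model in models:
            s, e = model.span
            blocks_list.append([(s, e)])
            strands.append(model.strand)
            chroms.append(model.chrom)
            weights.append(expr[model.gene_id] * pre_mrna_fraction)

    iso_lens = np.array([sum(e - s for s, e in b) for b in blocks_list])
    # read sampling is molecule-abundance x length, as in real sequencing, so
    # per-base coverage is proportional to abundance alone
    w = np.array(weights) * iso_lens
    w = w / w.sum()
    picks = rng.choice(len(blocks_list), size=n_reads, p=w)
    offsets = rng.integers(0, iso_lens[picks])

    rows = []
    for iso, t in zip(picks, offsets):
        blocks = blocks_list[iso]
        strand = strands[iso]
        remaining = int(t)
        for bs, be in blocks:
            blen = be - bs
            if remaining < blen:
                seg = min(read_length, blen - remaining)
                if strand == "+":
                    g0 = bs + remaining
                    rows.append((chroms[iso], strand, g0, g0 + seg))
                else:
                    g1 = be - remaining
                    rows.append((chroms[iso], strand, g1 - seg, g1))
                break
            remaining -= blen
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# truth export


def truth_sites_bed(truth: TruthSet, condition: str) -> pd.DataFrame:
    """Truth sites as BED6 rows (score = usage x 1000 for ``condition``)."""
    rows = [
        (
            s.chrom,
            s.cleavage_pos,
            s.cleavage_pos + 1,
            f"{s.gene_id}:{s.category}",
            int(round(s.usage_fraction_by_condition[condition] * 1000)),
            s.strand,
        )
        for s in truth.sites
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
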
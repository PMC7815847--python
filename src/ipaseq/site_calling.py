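"""PolyA-site calling: clustering of PASS-read cleavage positions, exclusion
and robustness filters, gene assignment and category annotation.

The cleavage coordinate convention is the 0-based position of the last
transcribed base; "upstream"/"downstream" are in transcription direction.
Clustering is single-linkage: sorted cleavage positions on the same
(contig, strand) are chained while consecutive gaps are at most the merge
window (24 nt by default). Annotation gives introns priority over 3'UTRs so
that unannotated intronic sites are not mislabelled, and sites of genes that
retain only a single site are re-annotated as 3'UTR.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binomtest

from .genome import Genome

LIBRARY_SEP = "."  # column label "<condition>.<replicate>"


def library_label(condition: str, replicate: int | str) -> str:
    return f"{condition}{LIBRARY_SEP}{replicate}"


@dataclass(frozen=True)
class ParamSet:
    """Single home for every numeric threshold of the analysis."""

    merge_window: int = 24            # nt, PASS-read cleavage clustering
    min_gene_rnaseq: int = 5          # counts, gene expressed in >=1 condition
    min_replicate_sum: int = 10       # counts, replicate sum in >=1 condition
    min_fpu: float = 0.10             # FPU in >=1 library
    window_halfwidth: int = 100       # bp, RNA-seq windows around a site
    fc_ipa_threads: float = 2.0       # FPU fold-change threshold (3'READS+)
    fc_rnaseq: float = 1.5            # RNA-seq window fold-change threshold
    fc_cpsf: float = 1.5              # knockdown fold-change threshold
    fc_distal: float = 1.5            # distal-usage fold-change threshold
    motif_extension: int = 200        # bp, sequence extraction around sites
    min_mapq: int = 10                # alignment quality floor
    min_insert: int = 22              # nt, shortest retained insert
    rescue_window: int = 20           # bp, genomic A-run rescue of T tails

    def __post_init__(self):
        for name in ("merge_window", "min_gene_rnaseq", "min_replicate_sum",
                     "window_halfwidth", "motif_extension", "min_insert",
                     "rescue_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_fpu <= 1:
            raise ValueError("min_fpu must be in (0, 1]")
        for name in ("fc_ipa_threads", "fc_rnaseq", "fc_cpsf", "fc_distal"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene: sorted disjoint exons plus 3'UTR intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "utr3", tuple(sorted(tuple(u) for u in self.utr3)))
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: invalid exon [{s}, {e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        )

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos < e


@dataclass(frozen=True)
class IntervalSet:
    """Labelled exclusion intervals (blacklist, retrotransposons, ...)."""

    label: str
    intervals: dict[str, tuple[tuple[int, int], ...]]

    def __post_init__(self):
        for chrom, ivs in self.intervals.items():
            for s, e in ivs:
                if s >= e:
                    raise ValueError(f"{self.label}/{chrom}: invalid interval [{s}, {e})")

    def tree(self) -> dict[str, IntervalTree]:
        return {
            chrom: IntervalTree.from_tuples(ivs)
            for chrom, ivs in self.intervals.items()
            if ivs
        }


@dataclass
class PolyASite:
    """A clustered cleavage site with per-library PASS-read counts."""

    site_id: str
    chrom: str
    strand: str
    position: int                     # representative cleavage coordinate
    span: tuple[int, int]             # [min, max+1) of member positions
    counts: dict[str, int]            # library label -> PASS-read count
    gene_id: str | None = None        # identifier | "multiple" | "none"
    category: str | None = None       # intron | utr3 | exon
    filter_flags: set[str] = field(default_factory=set)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# clustering


def cluster_ends(pass_positions: pd.DataFrame, merge_window: int = 24) -> list[PolyASite]:
    """Single-linkage clustering of PASS-read cleavage positions.

    ``pass_positions`` needs columns chrom, strand, position, condition,
    replicate (one row per PASS read). Cluster representative is the member
    position with the highest read count; ties break toward the 5'-most
    position in transcript orientation.
    """
    sites: list[PolyASite] = []
    if len(pass_positions) == 0:
        return sites
    df = pass_positions.copy()
    df["library"] = [
        library_label(c, r) for c, r in zip(df["condition"], df["replicate"])
    ]
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        per_pos = (
            grp.groupby(["position", "library"]).size().unstack(fill_value=0).sort_index()
        )
        positions = per_pos.index.to_numpy()
        breaks = np.where(np.diff(positions) > merge_window)[0] + 1
        for chunk in np.split(np.arange(len(positions)), breaks):
            member_pos = positions[chunk]
            counts_block = per_pos.iloc[chunk]
            totals = counts_block.sum(axis=1).to_numpy()
            best = totals == totals.max()
            candidates = member_pos[best]
            rep = candidates.min() if strand == "+" else candidates.max()
            lib_counts = counts_block.sum(axis=0)
            sites.append(
                PolyASite(
                    site_id="",
                    chrom=chrom,
                    strand=strand,
                    position=int(rep),
                    span=(int(member_pos.min()), int(member_pos.max()) + 1),
                    counts={lib: int(n) for lib, n in lib_counts.items() if n > 0},
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    for i, site in enumerate(sites):
        site.site_id = f"PAS{i:05d}"
    return sites


# ---------------------------------------------------------------------------
# filters


def apply_exclusion_filters(
    sites: list[PolyASite], interval_sets: list[IntervalSet]
) -> tuple[list[PolyASite], list[PolyASite]]:
    """Flag sites whose representative position falls in any exclusion set.

    Overlap is half-open on the single-base site interval [pos, pos+1); a site
    hit by several sets carries every label but is removed once.
    """
    trees = {s.label: s.tree() for s in interval_sets}
    retained, removed = [], []
    for site in sites:
        for label, per_chrom in trees.items():
            tree = per_chrom.get(site.chrom)
            if tree is not None and tree.overlaps(site.position, site.position + 1):
                site.filter_flags.add(label)
        (removed if site.filter_flags else retained).append(site)
    return retained, removed


def _span_trees(models: list[GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in models:
        s, e = m.span
        trees.setdefault((m.chrom, m.strand), IntervalTree()).addi(s, e, m.gene_id)
    return trees


def assign_genes(
    sites: list[PolyASite], models: list[GeneModel]
) -> tuple[list[PolyASite], list[PolyASite]]:
    """Assign each site to the unique same-strand gene span covering it.

    Sites covered by no gene get gene_id "none" (flag ``intergenic``); sites
    covered by two or more get "multiple" (flag ``multiple_genes``); both are
    removed.
    """
    trees = _span_trees(models)
    retained, removed = [], []
    for site in sites:
        tree = trees.get((site.chrom, site.strand))
        hits = sorted(iv.data for iv in tree[site.position]) if tree is not None else []
        if len(hits) == 0:
            site.gene_id = "none"
            site.filter_flags.add("intergenic")
            removed.append(site)
        elif len(hits) > 1:
            site.gene_id = "multiple"
            site.filter_flags.add("multiple_genes")
            removed.append(site)
        else:
            site.gene_id = hits[0]
            retained.append(site)
    return retained, removed


def flag_ambiguous_overlaps(
    sites: list[PolyASite], all_models: list[GeneModel]
) -> tuple[list[PolyASite], list[PolyASite]]:
    """Remove sites lying where >=2 gene spans of the *pre-filter* annotation
    overlap: even when only one of those genes survived earlier filters, reads
    there cannot be attributed unambiguously."""
    trees = _span_trees(all_models)
    retained, removed = [], []
    for site in sites:
        tree = trees.get((site.chrom, site.strand))
        n = len(tree[site.position]) if tree is not None else 0
        if n >= 2:
            site.filter_flags.add("ambiguous_overlap")
            removed.append(site)
        else:
            retained.append(site)
    return retained, removed


def apply_robustness_filters(
    sites: list[PolyASite],
    rnaseq_gene_counts: pd.DataFrame,
    params: ParamSet,
) -> tuple[list[PolyASite], list[PolyASite], dict[str, int]]:
    """Retain sites of robustly expressed genes with solid usage evidence.

    Three criteria, all required:
      1. host gene has >= ``min_gene_rnaseq`` RNA-seq counts in at least one
         condition (``rnaseq_gene_counts``: genes x conditions; genes missing
         from the table count as 0);
      2. the per-condition sum of replicate counts reaches
         ``min_replicate_sum`` in at least one condition;
      3. FPU >= ``min_fpu`` in at least one library.

    Returns (retained, removed, per-criterion removal counts); a site failing
    several criteria is counted once per criterion but removed once.
    """
    from .fpu_stats import compute_fpu

    counts, genes = sites_count_frame(sites)
    fpu = compute_fpu(counts, genes) if len(sites) else counts
    conditions = sorted({lib.split(LIBRARY_SEP)[0] for lib in counts.columns})
    stats = Counter()
    retained, removed = [], []
    for site in sites:
        failed = False
        gene_expr = 0
        if site.gene_id in rnaseq_gene_counts.index:
            gene_expr = int(rnaseq_gene_counts.loc[site.gene_id].max())
        else:
            stats["gene_missing_from_rnaseq"] += 1
        if gene_expr < params.min_gene_rnaseq:
            site.filter_flags.add("gene_not_expressed")
            stats["gene_not_expressed"] += 1
            failed = True
        rep_sums = [
            sum(n for lib, n in site.counts.items() if lib.split(LIBRARY_SEP)[0] == cond)
            for cond in conditions
        ]
        if not rep_sums or max(rep_sums) < params.min_replicate_sum:
            site.filter_flags.add("low_count")
            stats["low_count"] += 1
            failed = True
        site_fpu = fpu.loc[site.site_id]
        if not (site_fpu.dropna() >= params.min_fpu).any():
            site.filter_flags.add("low_fpu")
            stats["low_fpu"] += 1
            failed = True
        (removed if failed else retained).append(site)
    return retained, removed, dict(stats)


# ---------------------------------------------------------------------------
# annotation


def annotate_category(site: PolyASite, model: GeneModel) -> str:
    """Annotate intron / utr3 / exon with intron priority within the gene."""
    p = site.position
    if not model.contains(p):
        raise ValueError(
            f"site {site.site_id} at {site.chrom}:{p} outside span of {model.gene_id}"
        )
    if any(s <= p < e for s, e in model.introns):
        return "intron"
    if any(s <= p < e for s, e in model.utr3):
        return "utr3"
    return "exon"


def annotate_all(sites: list[PolyASite], models: list[GeneModel]) -> list[PolyASite]:
    by_id = {m.gene_id: m for m in models}
    for site in sites:
        site.category = annotate_category(site, by_id[site.gene_id])
    return sites


def reannotate_single_site_genes(
    sites: list[PolyASite],
) -> tuple[list[PolyASite], dict[str, int]]:
    """Sites of genes retaining exactly one site are labelled utr3.

    A lone surviving site almost always marks the gene's true 3' end even when
    the annotation places it in an intron or coding exon. Returns the sites
    and the number of adjustments split by prior category (idempotent).
    """
    per_gene = Counter(s.gene_id for s in sites)
    adjustments: Counter = Counter()
    for site in sites:
        if per_gene[site.gene_id] == 1 and site.category != "utr3":
            adjustments[site.category] += 1
            site.category = "utr3"
    return sites, dict(adjustments)


# ---------------------------------------------------------------------------
# motif scan


@dataclass(frozen=True)
class HexamerScanResult:
    n_sites: int
    n_hits: int
    fraction: float          # NaN when no sites
    expected_rate: float
    p_value: float


HEXAMER = "AATAAA"
_UPSTREAM_SCAN = 40  # bp immediately upstream of cleavage searched for the hexamer


def hexamer_scan(
    sites: list[PolyASite], genome: Genome, params: ParamSet
) -> HexamerScanResult:
    """Fraction of sites with AATAAA in the 40 bp upstream of cleavage.

    Sequence is extracted in transcript sense over +/- ``motif_extension`` bp
    (clipped at contig ends); the null hit rate for the binomial enrichment
    test uses the pooled base composition of those windows.
    """
    if not sites:
        return HexamerScanResult(0, 0, float("nan"), 0.0, 1.0)
    ext = params.motif_extension
    hits = 0
    base_counts = Counter()
    for site in sites:
        p = site.position
        if site.strand == "+":
            window = genome.fetch_sense(site.chrom, p - ext, p + ext + 1, "+", clamp=True)
            upstream = genome.fetch_sense(site.chrom, p - _UPSTREAM_SCAN + 1, p + 1, "+", clamp=True)
        else:
            window = genome.fetch_sense(site.chrom, p - ext, p + ext + 1, "-", clamp=True)
            upstream = genome.fetch_sense(site.chrom, p, p + _UPSTREAM_SCAN, "-", clamp=True)
        base_counts.update(window)
        if HEXAMER in upstream:
            hits += 1
    total = sum(base_counts[b] for b in "ACGT") or 1
    fa, ft = base_counts["A"] / total, base_counts["T"] / total
    q = fa**5 * ft  # P(AATAAA) at a single offset
    positions = _UPSTREAM_SCAN - len(HEXAMER) + 1
    p0 = min(1.0, 1.0 - (1.0 - q) ** positions)
    test = binomtest(hits, len(sites), p0, alternative="greater")
    return HexamerScanResult(len(sites), hits, hits / len(sites), p0, test.pvalue)


# ---------------------------------------------------------------------------
# tabular views


def sites_count_frame(sites: list[PolyASite]) -> tuple[pd.DataFrame, pd.Series]:
    """Site x library count matrix plus the site -> gene mapping."""
    libraries = sorted({lib for s in sites for lib in s.counts})
    counts = pd.DataFrame(
        [[s.counts.get(lib, 0) for lib in libraries] for s in sites],
        index=pd.Index([s.site_id for s in sites], name="site_id"),
        columns=libraries,
        dtype=float,
    )
    genes = pd.Series(
        [s.gene_id for s in sites], index=counts.index, name="gene_id", dtype=object
    )
    return counts, genes


def sites_to_frame(sites: list[PolyASite]) -> pd.DataFrame:
    """Flat site table (one row per site, one column per library)."""
    counts, genes = sites_count_frame(sites)
    meta = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "position": [s.position for s in sites],
            "strand": [s.strand for s in sites],
            "gene_id": genes,
            "category": [s.category for s in sites],
        },
        index=counts.index,
    )
    return pd.concat([meta, counts.astype(int)], axis=1)
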
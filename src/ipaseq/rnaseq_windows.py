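"""Strand-specific RNA-seq counting in fixed windows around polyA sites.

Reads are single-end genomic intervals (chrom, strand, start, end); a read
counts toward a window when the half-open intervals overlap, and only reads
on the site's transcript strand are ever counted. The upstream flank is the
``window_halfwidth``-wide window ending at (and including) the cleavage base;
the downstream flank starts immediately after it, both in transcript
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import UnknownContigError
from .site_calling import GeneModel, ParamSet, PolyASite

READ_COLUMNS = ["chrom", "strand", "start", "end"]


class _ReadIndex:
    """Sorted-endpoint index for O(log n) interval-overlap counting."""

    def __init__(self, reads: pd.DataFrame):
        self._starts: dict[tuple[str, str], np.ndarray] = {}
        self._ends: dict[tuple[str, str], np.ndarray] = {}
        if len(reads):
            for (chrom, strand), grp in reads.groupby(["chrom", "strand"]):
                self._starts[(chrom, strand)] = np.sort(grp["start"].to_numpy())
                self._ends[(chrom, strand)] = np.sort(grp["end"].to_numpy())

    def count(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Number of reads overlapping [start, end) on (chrom, strand)."""
        starts = self._starts.get((chrom, strand))
        if starts is None:
            return 0
        ends = self._ends.get((chrom, strand))
        a = int(np.searchsorted(starts, end, side="left"))   # reads with start < end
        b = int(np.searchsorted(ends, start, side="right"))  # reads with end <= start
        return a - b


def site_windows(site: PolyASite | object, halfwidth: int) -> dict[str, tuple[int, int]]:
    """Upstream / downstream / full windows around a site, transcript-oriented."""
    p, strand = site.position, site.strand
    if strand == "+":
        up = (p - halfwidth + 1, p + 1)
        down = (p + 1, p + halfwidth + 1)
    else:
        up = (p, p + halfwidth)
        down = (p - halfwidth, p)
    return {"up": up, "down": down, "window": (p - halfwidth, p + halfwidth + 1)}


def count_site_windows(
    read_positions: pd.DataFrame,
    sites: list[PolyASite],
    params: ParamSet,
    contigs: set[str] | None = None,
) -> pd.DataFrame:
    """Per-site window/upstream/downstream read counts for one condition
    (replicates pooled into ``read_positions``)."""
    index = _ReadIndex(read_positions)
    rows = []
    for site in sites:
        if contigs is not None and site.chrom not in contigs:
            raise UnknownContigError(f"site {site.site_id} on unknown contig {site.chrom!r}")
        w = site_windows(site, params.window_halfwidth)
        rows.append(
            (
                site.site_id,
                index.count(site.chrom, site.strand, *w["window"]),
                index.count(site.chrom, site.strand, *w["up"]),
                index.count(site.chrom, site.strand, *w["down"]),
            )
        )
    return pd.DataFrame(
        rows, columns=["site_id", "window_count", "upstream_count", "downstream_count"]
    ).set_index("site_id")


def window_log2fc(
    counts_A: pd.Series,
    counts_B: pd.Series,
    pseudocount: float = 1.0,
    libsize_A: int | None = None,
    libsize_B: int | None = None,
) -> pd.Series:
    """log2((B + pc) / (A + pc)) with B scaled by the mapped-reads ratio
    libsize_A / libsize_B before the ratio."""
    scale = 1.0
    if libsize_A and libsize_B:
        scale = libsize_A / libsize_B
    return np.log2((counts_B * scale + pseudocount) / (counts_A + pseudocount))


def gene_counts(read_positions: pd.DataFrame, models: list[GeneModel]) -> pd.Series:
    """Union-exon gene counting: a read counts toward a gene when it overlaps
    any exon on the matching strand; reads hitting exons of two or more genes
    are discarded as ambiguous."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in models:
        t = trees.setdefault((m.chrom, m.strand), IntervalTree())
        for s, e in m.exons:
            t.addi(s, e, m.gene_id)
    counts: dict[str, int] = {m.gene_id: 0 for m in models}
    for chrom, strand, start, end in read_positions[READ_COLUMNS].itertuples(index=False):
        tree = trees.get((chrom, strand))
        if tree is None:
            continue
        genes = {iv.data for iv in tree.overlap(start, end)}
        if len(genes) == 1:
            counts[genes.pop()] += 1
    return pd.Series(counts, name="count").sort_index()
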
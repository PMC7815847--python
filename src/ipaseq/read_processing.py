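"""From raw 3'-end-sequencing reads to PASS reads.

Stages: UMI removal and T-tail extraction, alignment (built-in exact aligner
or external SAM/BAM), MAPQ filtering, T-tail genome rescue, and PASS
classification. A read whose residual T tail retains at least two T's not
explained by genomic A's immediately downstream of the cleavage site is
Poly-A Site supporting (PASS); tails fully absorbed by genomic A-runs mark
internal priming and are discarded.

Tail rescue walks the tail from its insert-adjacent base outward, comparing
each tail base against successive genomic sense-strand bases downstream of
the provisional cleavage position (a tail T matches a genomic A; a tail non-T
matches only its complement). Each rescued base moves the cleavage position
one base downstream. Rescue rules are sometimes described as reading from
"the start of the T tail"; only the insert-adjacent end of the tail can abut
contiguous genomic sequence, so rescue proceeds from that end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .genome import Genome, UnknownContigError, complement_base


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.read_id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    umi: str
    tail: str                          # removed tail bases, read orientation
    tail_non_t_offset: int | None      # 0 = tail base adjacent to the insert
    insert: str

    @property
    def tail_length(self) -> int:
        return len(self.tail)


@dataclass(frozen=True)
class TrimRejection:
    read_id: str
    reason: str                        # "no_insert" | "short_insert"


@dataclass(frozen=True)
class AlignedSegment:
    read_id: str
    chrom: str
    genome_strand: str                 # strand the *insert* matches
    start: int
    end: int
    mapq: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: empty alignment interval")
        if self.mapq < 0:
            raise ValueError(f"{self.read_id}: negative mapq")


@dataclass(frozen=True)
class PassRead:
    read_id: str
    chrom: str
    transcript_strand: str
    cleavage_pos: int                  # 0-based last transcribed base
    unmappable_t: int

    def __post_init__(self):
        if self.unmappable_t < 2:
            raise ValueError("PASS requires at least two unmappable T's")


@dataclass(frozen=True)
class NonPass:
    read_id: str
    reason: str                        # internal_priming | insufficient_tail | tailless
    rescued_t: int
    unmappable_t: int
    cleavage_pos: int
    chrom: str
    transcript_strand: str


def trim_and_extract_tail(
    read: RawRead, umi_length: int = 4, min_insert: int = 22
) -> TrimmedRead | TrimRejection:
    """Remove the UMI, then the maximal leading T-run (one embedded non-T
    allowed provided at least one T follows it); the remainder is the insert.

    Reads shorter than the UMI are rejected "no_insert"; inserts shorter than
    ``min_insert`` are rejected "short_insert".
    """
    seq = read.sequence.upper()
    if len(seq) < umi_length:
        return TrimRejection(read.read_id, "no_insert")
    umi, rest = seq[:umi_length], seq[umi_length:]
    i = 0
    non_t_read_pos: int | None = None
    while i < len(rest):
        if rest[i] == "T":
            i += 1
        elif non_t_read_pos is None and i + 1 < len(rest) and rest[i + 1] == "T":
            non_t_read_pos = i
            i += 1
        else:
            break
    tail, insert = rest[:i], rest[i:]
    if len(insert) < min_insert:
        return TrimRejection(read.read_id, "short_insert")
    offset = None if non_t_read_pos is None else len(tail) - 1 - non_t_read_pos
    return TrimmedRead(read.read_id, umi, tail, offset, insert)


def naive_align(insert: str, genome: Genome, read_id: str = "") -> AlignedSegment | None:
    """Exact full-length search on both strands (test stand-in for an external
    end-to-end aligner). Unique hit: mapq 42; multiple hits: the first hit in
    (chrom, start, strand) order with mapq 0; no hit: None."""
    hits = genome.find_exact(insert)
    if not hits:
        return None
    best = hits[0]
    return AlignedSegment(
        read_id=read_id,
        chrom=best.chrom,
        genome_strand=best.strand,
        start=best.start,
        end=best.end,
        mapq=42 if len(hits) == 1 else 0,
    )


def load_alignments(
    path: str | Path,
    min_mapq: int = 10,
    genome: Genome | None = None,
) -> tuple[list[AlignedSegment], dict[str, int]]:
    """Read SAM/BAM, dropping unmapped, secondary/supplementary, and low-MAPQ
    records. Returns (segments, counts of each drop reason)."""
    import pysam

    stats: Counter = Counter()
    segments: list[AlignedSegment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            stats["records"] += 1
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats["secondary"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                stats["low_mapq"] += 1
                continue
            chrom = rec.reference_name
            if genome is not None and chrom not in genome.sequences:
                raise UnknownContigError(f"alignment on unknown contig: {chrom!r}")
            segments.append(
                AlignedSegment(
                    read_id=rec.query_name,
                    chrom=chrom,
                    genome_strand="-" if rec.is_reverse else "+",
                    start=rec.reference_start,
                    end=rec.reference_end,
                    mapq=rec.mapping_quality,
                )
            )
    return segments, dict(stats)


def resolve_cleavage_and_classify(
    trimmed: TrimmedRead,
    segment: AlignedSegment,
    genome: Genome,
    rescue_window: int = 20,
) -> PassRead | NonPass:
    """Rescue genomic-A-matched tail bases, fix the cleavage position, and
    classify the read as PASS (>=2 unmappable T's) or not.

    The transcript strand is opposite the insert's genome strand (the insert
    is the reverse complement of the transcript 3' end). Rescue is truncated
    at contig ends. A rescued non-T repositions the cleavage exactly like a
    rescued T; an unrescued non-T terminates rescue and never counts as an
    unmappable T.
    """
    tstrand = "-" if segment.genome_strand == "+" else "+"
    cleave = segment.end - 1 if tstrand == "+" else segment.start
    tail = trimmed.tail
    L = len(tail)
    rescued = 0
    while rescued < min(L, rescue_window):
        gpos = cleave + 1 if tstrand == "+" else cleave - 1
        sense = genome.base_sense(segment.chrom, gpos, tstrand)
        if sense is None:  # contig end
            break
        tail_base = tail[L - 1 - rescued]  # offset `rescued` from the insert
        if sense == complement_base(tail_base):
            rescued += 1
            cleave = gpos
        else:
            break
    unmappable = sum(1 for k in range(rescued, L) if tail[L - 1 - k] == "T")
    if unmappable >= 2:
        return PassRead(trimmed.read_id, segment.chrom, tstrand, cleave, unmappable)
    if L == 0:
        reason = "tailless"
    elif rescued > 0:
        reason = "internal_priming"
    else:
        reason = "insufficient_tail"
    return NonPass(trimmed.read_id, reason, rescued, unmappable, cleave, segment.chrom, tstrand)


# ---------------------------------------------------------------------------
# per-library orchestration

PARTITION_KEYS = (
    "input",
    "no_insert",
    "short_insert",
    "unaligned",
    "low_mapq",
    "tailless",
    "internal_priming",
    "insufficient_tail",
    "pass",
)


def process_reads(
    reads: Iterable[RawRead],
    genome: Genome,
    umi_length: int = 4,
    min_insert: int = 22,
    min_mapq: int = 10,
    rescue_window: int = 20,
    alignments: dict[str, AlignedSegment] | None = None,
) -> tuple[list[PassRead], dict[str, int]]:
    """Run a library through trim -> align -> MAPQ filter -> rescue/classify.

    ``alignments`` maps read_id to an externally produced AlignedSegment; when
    absent, the built-in exact aligner is used. Returns the PASS reads and the
    partition counts (every input read lands in exactly one category).
    """
    stats = Counter({k: 0 for k in PARTITION_KEYS})
    pass_reads: list[PassRead] = []
    for read in reads:
        stats["input"] += 1
        trimmed = trim_and_extract_tail(read, umi_length, min_insert)
        if isinstance(trimmed, TrimRejection):
            stats[trimmed.reason] += 1
            continue
        if alignments is not None:
            segment = alignments.get(read.read_id)
        else:
            segment = naive_align(trimmed.insert, genome, read_id=read.read_id)
        if segment is None:
            stats["unaligned"] += 1
            continue
        if segment.mapq < min_mapq:
            stats["low_mapq"] += 1
            continue
        outcome = resolve_cleavage_and_classify(trimmed, segment, genome, rescue_window)
        if isinstance(outcome, PassRead):
            stats["pass"] += 1
            pass_reads.append(outcome)
        else:
            stats[outcome.reason] += 1
    return pass_reads, dict(stats)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Phred+33 FASTQ reader yielding :class:`RawRead`."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield RawRead(rec.description or rec.id, str(rec.seq), qual)
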
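"""Reference sequence handling: in-memory contigs, FASTA I/O, exact-match search.

Coordinates are 0-based half-open throughout. ``strand`` is ``'+'`` or ``'-'``;
"sense" sequence means the sequence read 5'->3' on the given strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


class UnknownContigError(KeyError):
    """Raised when a contig name is not present in the reference."""


@dataclass(frozen=True, order=True)
class ExactHit:
    """A full-length exact occurrence of a query in the reference.

    ``strand`` is '+' if the query matches the forward genome sequence at
    [start, end), '-' if the query matches its reverse complement.
    """

    chrom: str
    start: int
    end: int
    strand: str


class Genome:
    """In-memory reference with a lazily built k-mer seed index.

    Suitable for the megabase-scale toy genomes used in simulation and in
    tests; real libraries should be aligned externally and ingested as
    SAM/BAM via :func:`ipaseq.read_processing.load_alignments`.
    """

    SEED_K = 20

    def __init__(self, sequences: dict[str, str]):
        self.sequences: dict[str, str] = {c: s.upper() for c, s in sequences.items()}
        self._index: dict[str, list[tuple[str, int]]] | None = None

    @property
    def contigs(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self._seq(chrom))

    def _seq(self, chrom: str) -> str:
        try:
            return self.sequences[chrom]
        except KeyError:
            raise UnknownContigError(f"unknown contig: {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int, clamp: bool = False) -> str:
        """Forward-strand sequence of [start, end). ``clamp`` truncates at contig ends."""
        seq = self._seq(chrom)
        if clamp:
            start, end = max(0, start), min(len(seq), end)
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def fetch_sense(self, chrom: str, start: int, end: int, strand: str, clamp: bool = False) -> str:
        """Sense-strand (5'->3') sequence of the interval [start, end)."""
        seq = self.fetch(chrom, start, end, clamp=clamp)
        return seq if strand == "+" else revcomp(seq)

    def base_sense(self, chrom: str, pos: int, strand: str) -> str | None:
        """Single sense-strand base at ``pos``; None outside the contig."""
        seq = self._seq(chrom)
        if pos < 0 or pos >= len(seq):
            return None
        base = seq[pos]
        return base if strand == "+" else complement_base(base)

    # -- exact search ------------------------------------------------------

    def _build_index(self) -> dict[str, list[tuple[str, int]]]:
        if self._index is None:
            k = self.SEED_K
            index: dict[str, list[tuple[str, int]]] = {}
            for chrom, seq in self.sequences.items():
                for i in range(len(seq) - k + 1):
                    index.setdefault(seq[i : i + k], []).append((chrom, i))
            self._index = index
        return self._index

    def find_exact(self, query: str) -> list[ExactHit]:
        """All full-length exact occurrences of ``query`` on either strand."""
        query = query.upper()
        hits: list[ExactHit] = []
        for strand, probe in (("+", query), ("-", revcomp(query))):
            if len(probe) >= self.SEED_K:
                index = self._build_index()
                for chrom, i in index.get(probe[: self.SEED_K], ()):
                    if self.sequences[chrom].startswith(probe, i):
                        hits.append(ExactHit(chrom, i, i + len(probe), strand))
            else:  # short queries: direct scan
                for chrom, seq in self.sequences.items():
                    i = seq.find(probe)
                    while i != -1:
                        hits.append(ExactHit(chrom, i, i + len(probe), strand))
                        i = seq.find(probe, i + 1)
        return sorted(hits)

    # -- I/O ---------------------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})
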
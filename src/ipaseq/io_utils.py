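"""Text-format plumbing: GTF, BED6, FASTQ, TSV and truth JSON.

All genomic coordinates are 0-based half-open in memory; GTF is converted to
1-based inclusive on write and back on read; BED is native 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .site_calling import GeneModel, IntervalSet, PolyASite, sites_to_frame
from .synthetic_data import FastqRecord, TruthSet, TruthSite


class BedParseError(ValueError):
    pass


# -- FASTQ ------------------------------------------------------------------


def write_fastq(records: list[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")


# -- GTF --------------------------------------------------------------------


def write_gtf(models: list[GeneModel], path: str | Path, source: str = "ipaseq") -> None:
    """gene / exon / three_prime_utr features, 1-based inclusive."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            s, e = m.span
            rows = [("gene", s, e)]
            rows += [("exon", a, b) for a, b in m.exons]
            rows += [("three_prime_utr", a, b) for a, b in m.utr3]
            for feature, a, b in rows:
                fh.write(
                    f"{m.chrom}\t{source}\t{feature}\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    exons: dict[str, list] = {}
    utr3: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip('"')
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            iv = (int(start) - 1, int(end))
            meta[gene_id] = (chrom, strand)
            if feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
            elif feature == "three_prime_utr":
                utr3.setdefault(gene_id, []).append(iv)
    return [
        GeneModel(gene_id=g, chrom=meta[g][0], strand=meta[g][1],
                  exons=tuple(exons.get(g, ())), utr3=tuple(utr3.get(g, ())))
        for g in sorted(exons)
    ]


# -- BED --------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path, min_fields: int = 3) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedParseError(f"{path}:{lineno}: expected >= {min_fields} fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end")
            row = fields[:6] + ["."] * (6 - len(fields))
            rows.append((row[0], start, end, row[3], row[4], row[5]))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_interval_set(path: str | Path, label: str) -> IntervalSet:
    bed = read_bed(path)
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in bed[["chrom", "start", "end"]].itertuples(index=False):
        intervals.setdefault(chrom, []).append((start, end))
    return IntervalSet(label=label, intervals={c: tuple(v) for c, v in intervals.items()})


def pass_reads_bed(pass_reads) -> pd.DataFrame:
    rows = [
        (r.chrom, r.cleavage_pos, r.cleavage_pos + 1, r.read_id, r.unmappable_t,
         r.transcript_strand)
        for r in pass_reads
    ]
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def sites_bed(sites: list[PolyASite]) -> pd.DataFrame:
    rows = [
        (s.chrom, s.position, s.position + 1, s.site_id, s.total_count, s.strand)
        for s in sites
    ]
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


# -- site table / TSV -------------------------------------------------------


def write_site_table(sites: list[PolyASite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t")


def read_site_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site_id")


# -- truth JSON -------------------------------------------------------------


def write_truth(truth: TruthSet, path: str | Path) -> None:
    payload = {
        "sites": [
            {
                "gene_id": s.gene_id,
                "chrom": s.chrom,
                "strand": s.strand,
                "cleavage_pos": s.cleavage_pos,
                "category": s.category,
                "usage": s.usage_fraction_by_condition,
            }
            for s in truth.sites
        ],
        "decoys": [list(d) for d in truth.decoys],
        "expression": truth.gene_expression_by_condition,
        "knockdown_responsive": sorted(truth.knockdown_responsive),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    return TruthSet(
        sites=[
            TruthSite(
                gene_id=s["gene_id"],
                chrom=s["chrom"],
                strand=s["strand"],
                cleavage_pos=s["cleavage_pos"],
                category=s["category"],
                usage_fraction_by_condition=s["usage"],
            )
            for s in payload["sites"]
        ],
        decoys=[tuple(d) for d in payload["decoys"]],
        gene_expression_by_condition=payload["expression"],
        knockdown_responsive=frozenset(payload.get("knockdown_responsive", ())),
    )
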
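"""Readers and writers for the plain-text formats used by the pipeline.

FASTA/FASTQ parsing goes through Biopython; GTF/GFF3/BED and the
collapsed-read format are simple enough that they are handled directly,
which keeps the coordinate conversions (GTF and GFF3 are 1-based
inclusive, BED and everything in memory are 0-based half-open) in one
place.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .intervals import GenomicInterval
from .sequences import normalize


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequence map; uppercased, U converted to T.

    Duplicate record names are an error.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA record name {rec.id!r} in {path}")
        out[rec.id] = normalize(str(rec.seq))
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Raw read sequences from a FASTQ file (qualities discarded)."""
    return [normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Collapsed reads


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct read sequence with its occurrence count."""

    sequence: str
    count: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"collapsed read count must be >= 1, got {self.count}")


_COLLAPSED_RE = re.compile(r"^(?P<id>.*)_x(?P<count>\d+)$")


def read_collapsed(path: str | Path) -> list[CollapsedRead]:
    """Collapsed FASTA with ``>name_x<count>`` headers."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED_RE.match(rec.id)
        if not m:
            raise ParseError(f"collapsed-read header without _x<count> suffix: {rec.id!r}")
        count = int(m.group("count"))
        if count < 1:
            raise ParseError(f"collapsed read {rec.id!r} has count {count} < 1")
        out.append(CollapsedRead(normalize(str(rec.seq)), count, m.group("id")))
    return out


def write_collapsed(reads: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            rid = r.id or f"read{i + 1}"
            fh.write(f">{rid}_x{r.count}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# Gene models / GTF


@dataclass
class GeneModel:
    """A transcript: ordered exons plus UTR sub-intervals, all 0-based."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> "GeneModel":
        self.exons.sort(key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ParseError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if self.exons:
            span = GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)
            for u in self.utr5 + self.utr3:
                if not span.contains(u):
                    raise ParseError(
                        f"transcript {self.transcript_id}: UTR {u} outside exon span"
                    )
        return self

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_UTR_FEATURES = {"five_prime_utr": "utr5", "three_prime_utr": "utr3", "UTR": None}


def read_gtf(
    path: str | Path, exclude_gene_ids: set[str] | None = None
) -> list[GeneModel]:
    """Parse exon/UTR/CDS rows of a GTF into GeneModel records.

    GTF is 1-based inclusive; stored intervals are 0-based half-open.
    ``exclude_gene_ids`` drops every row whose gene_id (or transcript_id)
    is listed — used to remove rows for already-annotated miRNA genes
    before genomic classification.
    """
    exclude = exclude_gene_ids or set()
    models: dict[str, GeneModel] = {}
    generic_utrs: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = cols[:9]
            if feature not in ("exon", "CDS") and feature not in _UTR_FEATURES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end {end1} < start {start1}")
            attrs = dict(_ATTR_RE.findall(attrs_s))
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid or "")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: missing transcript_id attribute")
            if gid in exclude or tid in exclude:
                continue
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            model = models.setdefault(tid, GeneModel(tid, gid, chrom, strand))
            if feature == "exon":
                model.exons.append(iv)
            elif feature == "CDS":
                model.cds.append(iv)
            elif feature == "five_prime_utr":
                model.utr5.append(iv)
            elif feature == "three_prime_utr":
                model.utr3.append(iv)
            else:  # generic "UTR": side resolved against the CDS afterwards
                generic_utrs.setdefault(tid, []).append(iv)
    for tid, utrs in generic_utrs.items():
        model = models[tid]
        if model.cds:
            cds_start = min(c.start for c in model.cds)
            for u in utrs:
                upstream = u.end <= cds_start
                five = upstream if model.strand != "-" else not upstream
                (model.utr5 if five else model.utr3).append(u)
        else:
            model.utr3.extend(utrs)
    return [m.validate() for m in models.values()]


# ---------------------------------------------------------------------------
# BED / GFF3 emission (and a minimal GFF3 reader)


def to_bed(intervals: Sequence[GenomicInterval], names: Sequence[str] | None = None) -> str:
    """BED6 text: 0-based half-open, strandless intervals get '.'."""
    lines = []
    for i, iv in enumerate(intervals):
        name = names[i] if names else "."
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t.\t{iv.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def to_gff3(
    records: Sequence[tuple[GenomicInterval, str, dict[str, str]]],
    source: str = "mirannot",
) -> str:
    """GFF3 text (1-based inclusive) from (interval, type, attributes) rows."""
    lines = ["##gff-version 3"]
    for iv, ftype, attrs in records:
        attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
        lines.append(
            f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attr_s}"
        )
    return "\n".join(lines) + "\n"


def to_gtf(models: Sequence[GeneModel], source: str = "mirannot") -> str:
    """GTF text (1-based inclusive) for exon/UTR/CDS rows of gene models."""
    lines = []
    for m in models:
        rows = (
            [("exon", e) for e in m.exons]
            + [("CDS", c) for c in m.cds]
            + [("five_prime_utr", u) for u in m.utr5]
            + [("three_prime_utr", u) for u in m.utr3]
        )
        for feature, iv in rows:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            lines.append(
                f"{m.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t{m.strand}\t.\t{attrs}"
            )
    return "\n".join(lines) + ("\n" if lines else "")


def read_gff3(path: str | Path) -> list[tuple[GenomicInterval, str, dict[str, str]]]:
    """Minimal GFF3 reader: (0-based interval, feature type, attributes)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols[:9]
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end {end1} < start {start1}")
            attrs = dict(
                kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv
            )
            strand = strand if strand in ("+", "-") else "."
            out.append((GenomicInterval(chrom, start1 - 1, end1, strand), ftype, attrs))
    return out
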
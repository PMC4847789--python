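"""Non-templated 3' additions (isomiRs) of mature miRNAs.

Detects single-base 3' extensions — adenylation (+A) and uridylation
(+U) — by comparing reads to the mature sequence directly (NTA reads do
not map to the genome) and then checking the extra base against the
genomic base immediately 3' of the mature locus: an extension identical
to the templated base is a genomic read-through, not an addition, and is
counted with the canonical reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .intervals import GenomicInterval
from .io import CollapsedRead
from .sequences import revcomp

ISOFORMS = ("CANONICAL", "PLUS_A", "PLUS_U", "PLUS_OTHER", "PLUS_UNDETERMINED")


@dataclass(frozen=True)
class IsoformRecord:
    mature_id: str
    tissue: str
    isoform: str
    count: int


def templated_next_base(
    locus: GenomicInterval, genome: Mapping[str, str]
) -> str | None:
    """Genomic base immediately 3' of the mature locus (strand-adjusted).

    None at a chromosome edge, where the non-templated status of an
    extension cannot be decided.
    """
    chrom = genome[locus.chrom]
    if locus.strand == "-":
        return revcomp(chrom[locus.start - 1]) if locus.start > 0 else None
    return chrom[locus.end] if locus.end < len(chrom) else None


def detect_nta(
    reads: Iterable[CollapsedRead],
    mature_id: str,
    mature_seq: str,
    locus: GenomicInterval,
    genome: Mapping[str, str],
    tissue: str = "",
) -> list[IsoformRecord]:
    """Partition mature-matching reads into canonical and +1 isoforms.

    Every read equal to the mature, or equal to mature plus one 3' base,
    is counted exactly once; longer tails are out of scope and ignored.
    """
    template = templated_next_base(locus, genome)
    counts = {iso: 0 for iso in ISOFORMS}
    L = len(mature_seq)
    for r in reads:
        if r.sequence == mature_seq:
            counts["CANONICAL"] += r.count
        elif len(r.sequence) == L + 1 and r.sequence[:-1] == mature_seq:
            extra = r.sequence[-1]
            if template is None:
                counts["PLUS_UNDETERMINED"] += r.count
            elif extra == template:
                counts["CANONICAL"] += r.count  # templated read-through
            elif extra == "A":
                counts["PLUS_A"] += r.count
            elif extra == "T":
                counts["PLUS_U"] += r.count
            else:
                counts["PLUS_OTHER"] += r.count
    return [
        IsoformRecord(mature_id, tissue, iso, n) for iso, n in counts.items() if n > 0
    ]


def isoform_table(records: Iterable[IsoformRecord]) -> pd.DataFrame:
    """(mature, tissue) x isoform count matrix; rows sum to matching reads."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame(columns=list(ISOFORMS))
    table = df.pivot_table(
        index=["mature_id", "tissue"],
        columns="isoform",
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    for iso in ISOFORMS:
        if iso not in table.columns:
            table[iso] = 0
    return table[list(ISOFORMS)].sort_index()


def flag_dominant_nta(table: pd.DataFrame) -> pd.DataFrame:
    """Rows where a non-templated isoform out-counts the canonical read."""
    if table.empty:
        return table
    nta = table[["PLUS_A", "PLUS_U"]].max(axis=1)
    return table[nta > table["CANONICAL"]]
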
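"""Small sequence helpers shared across stages.

Internal storage is DNA alphabet (T, never U), uppercase.  miRBase-style
inputs written as RNA are normalized on read.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, context: str = "sequence") -> str:
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{context} contains non-ACGT characters: {sorted(bad)}")
    return seq
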
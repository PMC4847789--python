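"""Pipeline configuration.

One flat key-value config (YAML on disk) holds every stage threshold with
its documented default, so no constant is hard-coded inside stage logic.
Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs
    genome: str = ""
    gtf: str = ""
    reads: dict[str, str] = field(default_factory=dict)  # tissue -> collapsed FASTA
    reference_hairpins: str = ""
    reference_matures: str = ""
    existing_annotation: str = ""  # optional GFF3
    outdir: str = "mirannot_out"
    seed: int = 0

    # preprocessing
    adapter: str = ""  # empty: libraries arrive pre-trimmed
    adapter_min_overlap: int = 8
    min_read_len: int = 16

    # discovery
    cluster_max_gap: int = 65
    excise_flank: int = 20
    precursor_min_len: int = 50
    precursor_max_len: int = 300
    discovery_min_cluster_count: int = 10

    # folding / structure
    min_loop: int = 3
    min_stem_pairs: int = 3
    validate_min_paired: float = 0.6
    loop_overlap_max: int = 2

    # homology
    homology_min_len: int = 60
    homology_min_identity: float = 0.8
    mature_max_mismatch: int = 1

    # curation
    peak_window: int = 2
    peak_min_fraction: float = 0.75
    peak_min_count: int = 10
    switching_min_total: int = 20

    # genomic context / miRtrons
    context_min_fraction: float = 0.15
    mirtron_len_min: int = 50
    mirtron_len_max: int = 120
    mirtron_min_coverage: float = 0.95
    mirtron_tail_max: int = 3

    # piRNA
    pirna_window: int = 10000
    pirna_min_size: int = 1000
    pirna_min_hits: float = 25.0
    pirna_min_sig: float = 0.5
    pirna_size_min: int = 24
    pirna_size_max: int = 32
    pirna_min_size_frac: float = 0.75
    pirna_max_gap: int = 500

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**data)
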
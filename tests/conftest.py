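"""Shared fixtures: the bundled synthetic study, generated once per session."""

from __future__ import annotations

from pathlib import Path

import pytest

from mirannot.config import PipelineConfig
from mirannot.pipeline import Pipeline, run_all
from mirannot.synthetic import TruthTable, generate_dataset, read_truth

DEMO_SEED = 42


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory) -> Path:
    outdir = tmp_path_factory.mktemp("demo")
    generate_dataset(outdir, seed=DEMO_SEED)
    return outdir


@pytest.fixture(scope="session")
def demo_truth(demo_dir) -> TruthTable:
    return read_truth(demo_dir)


@pytest.fixture(scope="session")
def demo_config(demo_dir) -> PipelineConfig:
    return PipelineConfig(
        genome=str(demo_dir / "genome.fa"),
        gtf=str(demo_dir / "annotation.gtf"),
        reads={
            p.stem: str(p) for p in sorted((demo_dir / "reads").glob("*.fa"))
        },
        reference_hairpins=str(demo_dir / "reference_hairpins.fa"),
        reference_matures=str(demo_dir / "reference_matures.fa"),
        existing_annotation=str(demo_dir / "existing_annotation.gff3"),
        outdir=str(demo_dir / "out"),
        seed=DEMO_SEED,
    )


@pytest.fixture(scope="session")
def demo_pipeline(demo_config) -> Pipeline:
    return run_all(demo_config)
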
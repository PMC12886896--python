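"""Shared fixtures: a tiny deterministic scenario and one full demo run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germ_epimem import synth
from germ_epimem.pipeline import PipelineConfig, make_demo, run_pipeline
from germ_epimem.synth import SyntheticTruth


@pytest.fixture(scope="session")
def toy_genome():
    return synth.simulate_genome(2, 50_000, seed=11)


@pytest.fixture(scope="session")
def toy_annotation(toy_genome):
    return synth.simulate_annotation(toy_genome, 30, gene_length=500, spacing=1000, seed=11)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """make_demo + run_pipeline once for the whole session (seed 1)."""
    demo_dir = tmp_path_factory.mktemp("demo")
    config_path = make_demo(demo_dir, seed=1)
    config = PipelineConfig.from_yaml(config_path)
    manifest = run_pipeline(config)
    truth = SyntheticTruth.load_tsv(demo_dir / "truth.tsv")
    return {
        "dir": demo_dir,
        "results": demo_dir / "results",
        "config": config,
        "manifest": manifest,
        "truth": truth,
    }


def read_gene_list(path) -> set[str]:
    return {line.strip() for line in path.read_text().splitlines() if line.strip()}
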
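"""Shared fixtures: a session-scoped synthetic dataset small enough for the
full suite to stay fast, plus its derived annotation objects."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pytest

from hoxcis import simulate as sim
from hoxcis.annotation import GenomeAnnotation, flatten_gene_models
from hoxcis.simulate import (
    CANONICAL_OVERRIDES,
    SimulationConfig,
    SimulatedCounts,
    ToyLocusLayout,
)


@dataclass
class Dataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    layout: ToyLocusLayout
    repeats: pd.DataFrame
    sim: SimulatedCounts
    manifest: dict
    out_dir: Path

    @property
    def models(self):
        return flatten_gene_models(
            self.annotation, canonical_overrides=CANONICAL_OVERRIDES
        )

    def sam(self, sample_id: str) -> str:
        return self.manifest["samples"][sample_id]["sam"]

    def bedgraph(self, sample_id: str, strand: str) -> str:
        key = "plus" if strand == "+" else "minus"
        return self.manifest["samples"][sample_id][key]


@pytest.fixture(scope="session")
def dataset(tmp_path_factory) -> Dataset:
    """Full 6-tissue x 2-genotype x 2-replicate dataset with alignments."""
    out = tmp_path_factory.mktemp("synthetic")
    config = SimulationConfig(seed=5, n_background_genes=30, library_size_mean=30_000)
    annotation, layout, repeats = sim.generate_annotation(config)
    simulated = sim.simulate_counts(annotation, config)
    manifest = sim.simulate_alignments(simulated, annotation, layout, config, str(out))
    return Dataset(
        config=config,
        annotation=annotation,
        layout=layout,
        repeats=repeats,
        sim=simulated,
        manifest=manifest,
        out_dir=out,
    )


@pytest.fixture(scope="session")
def counts_dataset() -> Dataset:
    """Larger count-only dataset (no alignments) for statistics tests."""
    config = SimulationConfig(seed=11, n_background_genes=400, chrom_length=500_000)
    annotation, layout, repeats = sim.generate_annotation(config)
    simulated = sim.simulate_counts(annotation, config)
    return Dataset(
        config=config,
        annotation=annotation,
        layout=layout,
        repeats=repeats,
        sim=simulated,
        manifest={},
        out_dir=Path("."),
    )
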
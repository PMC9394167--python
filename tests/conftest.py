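"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import pytest

from aptashape.config import PipelineConfig, SimulationConfig
from aptashape.samples import SampleRecord, SampleSheet
from aptashape.simulate import generate_pool, make_sample_sheet, simulate_branched_counts


@pytest.fixture()
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def tiny_sheet() -> SampleSheet:
    return SampleSheet(
        [
            SampleRecord("s1", "AAGGAAGG", "C", "training"),
            SampleRecord("s2", "CCTTCCTT", "Ta", "training"),
            SampleRecord("s3", "GGAATTCC", "T2T4", "training"),
        ]
    )


@pytest.fixture(scope="session")
def small_simulation():
    """A small noise-free-ish simulated dataset shared across tests."""
    cfg = SimulationConfig(
        n_families=3,
        members_per_family=3,
        n_singletons=40,
        read_depth=2000,
        n_control=3,
        n_ta=3,
        n_t2t4=3,
        seed=7,
    )
    truth = generate_pool(cfg)
    sheet = make_sample_sheet(cfg)
    counts, probs = simulate_branched_counts(truth, sheet, cfg)
    return cfg, truth, sheet, counts, probs
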
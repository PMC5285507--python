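import pytest

from kredit import SimulationConfig, simulate_iclap_library, simulate_world
from kredit.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic maxicircle world (18 transcripts, seed 42)."""
    return simulate_world(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_run(default_world):
    """Default full run: 50,000 tags through the complete pipeline.

    Returns (reads, ground truth, pipeline result); the library is
    demultiplexed under barcode ACGT.
    """
    config = default_world.config
    reads, truth = simulate_iclap_library(
        config, default_world.pool, default_world.extents, barcode="ACGT", n_tags=50_000
    )
    result = run_pipeline(reads, default_world.pair, config.adapter, {"ACGT": "iclap"})
    return reads, truth, result


@pytest.fixture(scope="session")
def small_world():
    """A reduced world for fast unit tests."""
    return simulate_world(
        SimulationConfig(
            seed=11,
            genome_length=9_000,
            n_pan_edited=3,
            n_minimally_edited=2,
            n_never_edited=2,
            transcript_length_range=(400, 600),
            molecules_per_transcript=10,
        )
    )
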
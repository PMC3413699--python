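import numpy as np
import pytest

from transnp import SimConfig, run_discovery
from transnp.simulate import generate_transcriptome, simulate_reads


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but fully featured simulated experiment."""
    return SimConfig(n_transcripts=6, transcript_length_range=(800, 1200), seed=42)


@pytest.fixture(scope="session")
def small_run(small_config):
    """One end-to-end synthetic discovery run shared across tests."""
    return run_discovery(small_config)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Error-free reads: downstream results must match truth exactly."""
    return SimConfig(n_transcripts=6, transcript_length_range=(800, 1200),
                     per_base_error=0.0, homopolymer_indel_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_sim(clean_config):
    transcripts, truth = generate_transcriptome(clean_config)
    reads, origin = simulate_reads(transcripts, truth, clean_config)
    return transcripts, truth, reads, origin


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
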
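import numpy as np
import pytest

from nucdyn.io_annotation import GeneModel, ProbeTrack
from nucdyn.nucleosome_calling import StringencyConfig
from nucdyn.synthetic_data import SimulationConfig, simulate_dataset


def make_track(positions, minima, chromosome="chr1", replicates=3):
    """Track whose per-probe replicate minimum equals ``minima``.

    Replicate 1 carries the minimum; the others sit 0.5 above it, so the
    min-over-replicates rule sees exactly ``minima``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    minima = np.asarray(minima, dtype=float)
    values = np.tile(minima[:, None], (1, replicates)) + 0.5
    values[:, 0] = minima
    return ProbeTrack(chromosome, positions, values)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture(scope="session")
def default_stringency():
    return StringencyConfig()


@pytest.fixture(scope="session")
def dataset():
    """Small seeded synthetic dataset shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def recovery_dataset():
    """Dataset at 2.0 log2 signal separation and 0.3 noise for recovery checks."""
    cfg = SimulationConfig(
        seed=11, noise_sd=0.3, background_mean=-1.5, nucleosome_signal_mean=0.5
    )
    return simulate_dataset(cfg)


@pytest.fixture
def forward_gene():
    return GeneModel(
        gene_id="GF",
        chromosome="chr1",
        strand="forward",
        tss=5000,
        start_codon=5120,
        stop_codon=5800,
        mrna_end=6000,
    )


@pytest.fixture
def reverse_gene():
    return GeneModel(
        gene_id="GR",
        chromosome="chr1",
        strand="reverse",
        tss=5000,
        start_codon=4880,
        stop_codon=4200,
        mrna_end=4000,
    )
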
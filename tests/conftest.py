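import numpy as np
import pytest

from temasker.kmer_detector import detect_repeats
from temasker.synthetic_fixtures import SimulationParams, simulate_genome


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study genome (1 Mbp, 5 families x 20 copies, 2%)."""
    return simulate_genome(SimulationParams())


@pytest.fixture(scope="session")
def default_detection(default_dataset):
    """Repeats called on the default genome with the default detector config."""
    repeats, cfg = detect_repeats(default_dataset.genome)
    return repeats, cfg


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 200 kb genome with 4 equal-length families for annotation tests."""
    return simulate_genome(
        SimulationParams(
            genome_length=200_000,
            n_families=4,
            copies_per_family=10,
            family_length_range=(1000, 1000),
            n_genes=40,
            n_te_genes=8,
            n_nlr=4,
            seed=11,
        )
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate_subs(rng: np.random.Generator, seq: str, n_subs: int, margin: int = 0) -> str:
    """Substitute exactly n_subs interior positions (avoiding the ends)."""
    pos = rng.choice(np.arange(margin, len(seq) - margin), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)
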
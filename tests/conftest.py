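"""Shared fixtures: small synthetic genomes with planted ground truth."""

import numpy as np
import pytest

from repeatscape.references import default_library
from repeatscape.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def refs():
    return default_library()


@pytest.fixture(scope="session")
def small_sim():
    """A 400-kb genome with 8 young LTR elements and 2 MITEs."""
    config = SimulationConfig(genome_length=400_000, n_ltr_elements=8,
                              n_tir_elements=2, age_range=(0.0, 1.5e6), seed=11)
    return simulate_genome(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)


def reciprocal_overlap(a_start, a_end, b_start, b_end, frac=0.8) -> bool:
    inter = max(0, min(a_end, b_end) - max(a_start, b_start))
    return inter >= frac * (a_end - a_start) and inter >= frac * (b_end - b_start)
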
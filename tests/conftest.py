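import numpy as np
import pytest

from nadscope.cohort import SimulationConfig, simulate_capture, simulate_truth
from nadscope.contacts import ContactMatrix
from nadscope.genome import annotate, build_bins

TOY_SIZES = {"1": 1_500_000, "2": 1_200_000, "12": 900_000, "X": 600_000}


@pytest.fixture
def toy_bins():
    """4-chromosome toy genome at 100 kb: 15 + 12 + 9 + 6 = 42 bins."""
    return build_bins(TOY_SIZES, 100_000)


@pytest.fixture
def toy_annotation(toy_bins):
    return annotate(toy_bins, rdna_chroms={"12"})


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (53 cells, scaled-down mouse-like genome)."""
    config = SimulationConfig(seed=1)
    truth = simulate_truth(config)
    matrix, _, _ = simulate_capture(truth, config)
    return config, truth, matrix


@pytest.fixture(scope="session")
def hybrid_cohort():
    """Allele-resolved cohort, 50 cells, noise-free and deterministic contacts."""
    config = SimulationConfig(
        n_cells=50,
        allele_mode="hybrid",
        contamination_fraction=0.0,
        n_populations=1,
        seed=7,
    )
    truth = simulate_truth(config)
    # force deterministic contacts so classification reflects the allele
    # regimes rather than capture noise
    truth.contact_prob[truth.contact_prob > 0] = 1.0
    matrix, maternal, paternal = simulate_capture(truth, config)
    return config, truth, matrix, maternal, paternal


def toy_matrix(bins, columns) -> ContactMatrix:
    states = np.asarray(columns, dtype=np.uint8).T
    cells = [f"c{i}" for i in range(states.shape[1])]
    return ContactMatrix(bins=bins, cells=cells, states=states)
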
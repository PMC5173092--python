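import numpy as np
import pandas as pd
import pytest

from cernet.interactions import interaction_set_from_frame
from cernet.simulate import SimulationConfig, simulate_cohort


def make_interactions(rows):
    """rows: iterable of (mirna, gene, gene_class, evidence)."""
    return interaction_set_from_frame(
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "gene_class", "evidence"])
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by several test modules."""
    config = SimulationConfig(
        n_mirnas=100,
        n_lncrnas=10,
        n_mrnas=30,
        n_samples=120,
        n_true_pairs=4,
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
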
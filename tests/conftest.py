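import warnings

import numpy as np
import pytest

from leafnet import synthetic as syn

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_genome():
    """Desk-scale genome: 2 x 1 Mb, 200 genes."""
    return syn.generate_genome(
        n_chroms=2, chrom_length=1_000_000, gc=0.5, n_genes=200, seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return syn.plant_regulatory_landscape(
        small_genome, n_tfs=20, seed=11, target_fraction=0.5
    )


@pytest.fixture(scope="session")
def small_peaks(small_genome, small_truth):
    return syn.generate_peaks(small_genome, small_truth, seed=11)


@pytest.fixture(scope="session")
def small_peaks_no_cobind(small_genome, small_truth):
    return syn.generate_peaks(
        small_genome, small_truth, seed=11, plant_cobinding=False
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
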
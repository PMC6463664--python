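import numpy as np
import pandas as pd
import pytest

from wheatrec.io_formats import GenomeLayout, GenotypeMatrix
from wheatrec.synthetic_data import SimConfig, simulate_ssd_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions shrunk ~10x for unit tests: same marker
    and coverage densities, shorter chromosomes."""
    return SimConfig(
        n_chroms=3,
        chrom_length=60_000_000,
        n_lines=8,
        array_markers=62,
        gc_class_bounds=((20, 2_000), (2_000, 10_000), (10_000, 500_000),
                         (1_000_000, 5_000_000)),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_ssd_population(small_config)


def make_matrix(markers, lines, calls):
    """Helper: build a GenotypeMatrix from (chrom, pos, id) tuples."""
    df = pd.DataFrame(markers, columns=["chrom", "pos", "marker_id"])
    return GenotypeMatrix(markers=df, lines=lines, calls=np.asarray(calls, dtype=np.int8))


@pytest.fixture
def layout_600():
    return GenomeLayout(names=("c1",), lengths={"c1": 600_000_000})
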
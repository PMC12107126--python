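import numpy as np
import pytest

from cnvscreen import (
    BinGrid,
    ChromRecord,
    GenomeIndex,
    SimulationConfig,
    make_bins,
    make_rhino_like_index,
    simulate_bin_counts,
)


@pytest.fixture
def small_index() -> GenomeIndex:
    """A toy genome: three autosomes, an X, and one Y scaffold."""
    return GenomeIndex(
        [
            ChromRecord("chr1", 5_000_000, "autosome"),
            ChromRecord("chr2", 3_500_000, "autosome"),
            ChromRecord("chr3", 2_000_000, "autosome"),
            ChromRecord("chrX", 2_500_000, "X"),
            ChromRecord("chrY_scaffold_1", 400_000, "Y"),
        ]
    )


@pytest.fixture
def small_grid(small_index) -> BinGrid:
    return make_bins(small_index, bin_size=1_000_000)


@pytest.fixture(scope="session")
def rhino_index() -> GenomeIndex:
    return make_rhino_like_index(seed=11)


@pytest.fixture(scope="session")
def rhino_grid(rhino_index) -> BinGrid:
    return make_bins(rhino_index)


def simulate_counts(index, grid, seed, cnvs=(), sex="XY", mean_depth=75.0, **kw):
    config = SimulationConfig(
        index=index, seed=seed, cnvs=tuple(cnvs), sex=sex, mean_depth=mean_depth, **kw
    )
    return simulate_bin_counts(config, grid)


@pytest.fixture
def sim():
    return simulate_counts
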
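import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from paleogt import (
    PanelConfig,
    PlantedSegment,
    make_site_table,
    simulate_panel,
    simulate_truth,
)

#: ROH tracts planted in the shared truth set (sample ind0); all >= 2 Mb and
#: disjoint from the IBD tracts below.
ROH_PLAN = (
    PlantedSegment("ROH", ("ind0",), "chr1", 10_000_000, 16_000_000),
    PlantedSegment("ROH", ("ind0",), "chr1", 30_000_000, 32_500_000),
    PlantedSegment("ROH", ("ind0",), "chr2", 20_000_000, 23_000_000),
)

#: IBD tracts planted between ind0 and ind1; all >= 5 cM at 1 cM/Mb, summing
#: comfortably past the 21 cM relatedness floor even after boundary jitter.
IBD_PLAN = (
    PlantedSegment("IBD", ("ind0", "ind1"), "chr1", 20_000_000, 28_000_000),
    PlantedSegment("IBD", ("ind0", "ind1"), "chr1", 40_000_000, 48_000_000),
    PlantedSegment("IBD", ("ind0", "ind1"), "chr2", 5_000_000, 13_000_000),
)


@pytest.fixture(scope="session")
def panel100k():
    """Default desk-scale panel: 2 x 50 Mb chromosomes, 100k sites, 1 cM/Mb."""
    return simulate_panel(PanelConfig(seed=11))


@pytest.fixture(scope="session")
def planted_truth(panel100k):
    """Two truth diploids with the planted ROH and IBD segments above."""
    return simulate_truth(
        panel100k, 2, roh_plan=ROH_PLAN, ibd_plan=IBD_PLAN, seed=12
    )


@pytest.fixture(scope="session")
def small_panel():
    """Fast panel for I/O and unit tests: 2 x 5 Mb, 4k sites."""
    return simulate_panel(
        PanelConfig(
            n_sites=4000,
            chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000},
            seed=21,
        )
    )


@pytest.fixture
def tiny_sites():
    """Hand-sized site table on one chromosome."""
    return make_site_table(
        ["chr1"] * 4,
        [100, 200, 300, 400],
        ["A", "C", "G", "T"],
        ["G", "T", "A", "A"],
        [0.1, 0.3, 0.45, 0.02],
    )
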
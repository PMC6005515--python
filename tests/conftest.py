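import numpy as np
import pandas as pd
import pytest

import guidescreen as gs
from guidescreen.library import NTC_GENE


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny two-arm screen: 12 genes x 4 guides + 4 NTCs, days 0/21."""
    return gs.SimulationConfig(
        n_genes=12,
        guides_per_gene=4,
        n_ntc=4,
        n_replicates=3,
        arms=("vehicle", "MEKi"),
        days=(0, 21),
        coverage=500,
        dispersion=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_lib(small_cfg):
    return gs.simulate_library(small_cfg)


@pytest.fixture(scope="session")
def neutral_screen(small_cfg, small_lib):
    """Counts with no planted effects."""
    return gs.simulate_screen(small_lib, gs.EffectTable(), small_cfg)


@pytest.fixture
def toy_library():
    """Hand-built 5-guide library (2 genes + 1 NTC) with 8-nt spacers."""
    table = pd.DataFrame(
        {
            "gene": ["GA", "GA", "GB", "GB", NTC_GENE],
            "sequence": ["ACGTACGT", "TTTTAAAA", "CCCCGGGG", "GATCGATC", "AAAACCCC"],
            "is_ntc": [False, False, False, False, True],
        },
        index=pd.Index(["gA_1", "gA_2", "gB_1", "gB_2", "ntc_1"], name="guide_id"),
    )
    return gs.GuideLibrary(table)


@pytest.fixture
def toy_counts(toy_library):
    rng = np.random.default_rng(3)
    samples = pd.DataFrame(
        {
            "replicate": ["rep1", "rep1", "rep2", "rep2"],
            "arm": ["vehicle", "MEKi", "vehicle", "MEKi"],
            "day": [21, 21, 21, 21],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    counts = pd.DataFrame(
        rng.poisson(200, size=(5, 4)),
        index=toy_library.guide_ids,
        columns=samples.index,
    )
    return gs.CountMatrix(counts, samples)
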
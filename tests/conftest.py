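import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mosaicscan.genomic_io import GroupMap


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def ten_sample_groups():
    """Ten samples split 2/4/3/1 over P1/P2/P3/OUT."""
    return GroupMap(
        {
            "s0": "P1",
            "s1": "P1",
            "s2": "P2",
            "s3": "P2",
            "s4": "P2",
            "s5": "P2",
            "s6": "P3",
            "s7": "P3",
            "s8": "P3",
            "s9": "OUT",
        }
    )


@pytest.fixture
def small_sim_cfg():
    from mosaicscan.synthetic_data import SimulationConfig

    return SimulationConfig(
        chrom_lengths={"chr1": 400_000},
        tract_mean_len=20_000,
        n_genes=20,
        seed=11,
    )
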
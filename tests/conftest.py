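import numpy as np
import pytest

from petsrtm import SimConfig, RegionSpec, simulate_reference_tac


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def ref_tac(default_config):
    """Noiseless cerebellar reference TAC on the 26-frame study schedule."""
    return simulate_reference_tac(default_config)


@pytest.fixture(scope="session")
def small_config():
    """Tiny cohort (2+2 subjects, 12 frames over 40 min) for fast end-to-end runs."""
    return SimConfig(
        frame_durations=(0.5,) * 4 + (2.0,) * 4 + (7.5,) * 4,
        regions={
            "Pu": RegionSpec(2.08, 0.19, 21.6, 5.1),
            "VSt": RegionSpec(2.48, 0.19, 26.5, 7.7),
        },
        ddbp={
            "20 mg": {"Pu": (16.4, 11.3), "VSt": (13.8, 14.1)},
            "40 mg": {"Pu": (36.4, 7.7), "VSt": (22.6, 20.3)},
        },
        n_per_group={"20 mg": 2, "40 mg": 2},
    )
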
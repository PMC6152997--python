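import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from premascan import PlantSpec, ScanConfig, plant_locus


@pytest.fixture(scope="session")
def default_config():
    return ScanConfig()


@pytest.fixture(scope="session")
def group4_locus():
    """A planted single-dominant-repeat locus (Group 4 by construction)."""
    return plant_locus(PlantSpec(arm_len=6, arm_gc=4, intervening_len=0,
                                 n_decoys=0, seed=11))


@pytest.fixture(scope="session")
def group3_locus():
    """Planted locus with a near-equal decoy pair (Group 3)."""
    return plant_locus(PlantSpec(arm_len=4, arm_gc=2, intervening_len=2,
                                 n_decoys=1, decoy_strength=1.0, seed=7))


ARCHETYPES = {
    4: PlantSpec(arm_len=6, arm_gc=4, intervening_len=0, n_decoys=0),
    3: PlantSpec(arm_len=4, arm_gc=2, intervening_len=2,
                 n_decoys=1, decoy_strength=1.0),
    2: PlantSpec(arm_len=4, arm_gc=2, intervening_len=8, n_decoys=0),
    1: PlantSpec(arm_len=4, arm_gc=2, intervening_len=8,
                 n_decoys=1, decoy_strength=1.0),
}
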
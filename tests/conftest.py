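from __future__ import annotations

import pytest

from myoscreen.screen_data import WellRole
from myoscreen.synthetic_screen import (
    PlantedEffect,
    SimulationConfig,
    default_library,
    simulate_screen,
)

# A reduced single-plate layout for fast unit tests: same role structure as
# the real screen, fewer wells.
SMALL_LAYOUT = (
    {
        WellRole.GM_NEG_CONTROL: 8,
        WellRole.DM_I_POS_CONTROL: 8,
        WellRole.MOCK: 2,
        WellRole.UNIVERSAL_CONTROL: 1,
        WellRole.KIF11_CONTROL: 1,
        WellRole.EXPERIMENTAL: 20,
    },
)


@pytest.fixture(scope="session")
def small_library():
    return default_library(20)


@pytest.fixture(scope="session")
def null_screen_small(small_library):
    """A seeded screen with no planted effects on the reduced layout."""
    config = SimulationConfig(seed=11)
    return simulate_screen(config, small_library, SMALL_LAYOUT)


@pytest.fixture(scope="session")
def planted_screen_small(small_library):
    """Reduced screen with 5 strong planted hits and 3 anti-proliferative genes."""
    genes = small_library.gene_symbols
    planted = {g: PlantedEffect(40.0, 0.3) for g in genes[:5]}
    planted.update({g: PlantedEffect(1.0, 0.3) for g in genes[5:8]})
    config = SimulationConfig(seed=12, planted_hits=planted)
    return simulate_screen(config, small_library, SMALL_LAYOUT)
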
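import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles helpers

from ohnodiv.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A compact but fully featured study: 2 species, 120 pillars."""
    return SimConfig(
        seed=11,
        n_species=2,
        n_pillars=120,
        frac_retained_pairs=0.4,
        frac_de_pairs=0.3,
        scaffold_length=120_000,
    )


@pytest.fixture(scope="session")
def study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def multispecies_study():
    """Focal + 8 non-WGH species + 2 outgroups, for profile clustering."""
    cfg = SimConfig(
        seed=7,
        n_species=11,
        n_outgroups=2,
        n_pillars=80,
        frac_retained_pairs=0.5,
        frac_de_pairs=0.6,
        scaffold_length=120_000,
    )
    return simulate_study(cfg)
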
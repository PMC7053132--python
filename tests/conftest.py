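import numpy as np
import pytest
from hypothesis import settings

from demecycles import (
    AntibioticParams,
    PyoverdineParams,
    StrainParams,
    WorldConfig,
)

settings.register_profile("derandomized", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("derandomized")


@pytest.fixture
def neutral_world():
    """Single neutral strain, dS0phi = 60 (dilution-line benchmark)."""
    return WorldConfig(
        strains=(StrainParams(),), s0_phi=1e5, t_mix=24.0, d=6e-4
    )


@pytest.fixture
def neutral_pair_world():
    """Two identical strains (neutral composition direction)."""
    return WorldConfig(
        strains=(StrainParams(), StrainParams()), s0_phi=1e5, t_mix=24.0, d=6e-4
    )


@pytest.fixture
def tradeoff_world():
    """Slow-but-efficient strain 1 against a neutral reference."""
    return WorldConfig(
        strains=(StrainParams(delta_alpha=-0.1, delta_phi=0.2), StrainParams()),
        s0_phi=1e5,
        t_mix=24.0,
        d=1.05e-5,
    )


@pytest.fixture
def antibiotic_world():
    """Enzyme producer with a small growth cost; antibiotic above the MIC."""
    return WorldConfig(
        strains=(StrainParams(delta_alpha=-0.02, rho=5e-3), StrainParams()),
        s0_phi=1e5,
        t_mix=24.0,
        d=6e-4,
        interaction=AntibioticParams(b0=1.25, kappa=2.0, gamma=2.0),
    )


@pytest.fixture
def pyoverdine_world():
    """Pyoverdine producer with a small growth cost, saturating yield boost 2x."""
    return WorldConfig(
        strains=(StrainParams(delta_alpha=-1e-3, rho=1e-3), StrainParams()),
        s0_phi=1e5,
        t_mix=24.0,
        d=6e-4,
        interaction=PyoverdineParams(sigma=2.0),
    )
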
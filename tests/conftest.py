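import pytest

from biogel import ChainSpec, ParticleShape


@pytest.fixture
def soft_chain() -> ChainSpec:
    """A loosely stretched chain with extensibility scale kappa = 0.1."""
    return ChainSpec.from_kappa(0.1)


@pytest.fixture
def sphere() -> ParticleShape:
    return ParticleShape(rho=1.0, xi=1.0)


@pytest.fixture
def ellipsoid() -> ParticleShape:
    return ParticleShape(rho=1.0, xi=3.0)


@pytest.fixture
def mucus_observations():
    """The three mucus rows of the bundled literature table."""
    from biogel.io import bundled_observations

    return [o for o in bundled_observations() if "mucus" in o.name]
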
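import pytest

from ecovoi import (
    EcosystemConfig,
    SweepGrid,
    build_motif,
    default_grid,
    run_sweep,
)


@pytest.fixture(scope="session")
def linear_web():
    return build_motif("linear", 4)


@pytest.fixture(scope="session")
def omnivory_web():
    return build_motif("omnivory", 4)


@pytest.fixture
def chain2_config():
    """Two-species chain, small enough for exhaustive oracles."""
    web = build_motif("custom", 2, edges=[(1, 2)], n_species=2)
    return EcosystemConfig(web=web, alpha=0.6, p0=(0.8, 0.7), b=0.5, gamma=0.95)


@pytest.fixture
def chain3_config():
    """Three-species chain for exhaustive-enumeration cross-checks."""
    web = build_motif("custom", 3, edges=[(1, 2), (2, 3)], n_species=3)
    return EcosystemConfig(web=web, alpha=0.5, p0=0.8, b=0.6, gamma=0.95)


@pytest.fixture
def peak_service_config(omnivory_web):
    """The high-feedback, high-predation service configuration."""
    return EcosystemConfig(
        web=omnivory_web, alpha=0.8, p0=0.8, b=0.9, objective="service"
    )


@pytest.fixture(scope="session")
def small_grid():
    """A 2x2x2x2x2 grid for fast sweep behaviour tests."""
    return SweepGrid(
        motifs=("linear", "omnivory"),
        trophic_levels=(1, 4),
        alphas=(0.3, 0.8),
        p0s=(0.5, 0.9),
        bs=(0.3, 0.9),
    )


@pytest.fixture(scope="session")
def service_sweep():
    """The full factorial sweep under the service objective (shared)."""
    return run_sweep(default_grid(), objective="service")


@pytest.fixture(scope="session")
def biodiversity_sweep():
    """The full factorial sweep under the biodiversity objective (shared)."""
    return run_sweep(default_grid(), objective="biodiversity")
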
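import pytest

from methanergy import (
    EnergyScenario,
    SpeciatedFluid,
    default_reaction_catalog,
    load_seo_fixture,
    scenario_grid,
)
from methanergy.speciation import SpeciesState


@pytest.fixture(scope="session")
def field_sites():
    return load_seo_fixture()


@pytest.fixture(scope="session")
def springs(field_sites):
    return [s for s in field_sites if s.site_type == "spring"]


@pytest.fixture(scope="session")
def catalog():
    return default_reaction_catalog()


@pytest.fixture(scope="session")
def spring_grid(springs):
    """Energy-density grid over the three hyperalkaline springs with the
    study's default scenario set."""
    return scenario_grid(springs)


def make_fluid(activities: dict, T_K: float = 298.15, site_id: str = "test") -> SpeciatedFluid:
    """Minimal speciated fluid carrying prescribed activities (gamma = 1)."""
    species = {
        name: SpeciesState(molality=a, gamma=1.0, activity=a)
        for name, a in activities.items()
    }
    return SpeciatedFluid(
        site_id=site_id,
        temperature_K=T_K,
        pH=7.0,
        ionic_strength_molal=0.0,
        species=species,
        iterations=1,
        residual=0.0,
    )


@pytest.fixture
def fluid_factory():
    return make_fluid


@pytest.fixture
def default_scenario():
    return EnergyScenario()
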
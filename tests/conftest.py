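import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iscarod.builder import (
    detect_cluster_sites,
    expand_supercell,
    extract_rod,
    place_clusters,
)
from iscarod.synthetic import (
    FixtureSpec,
    make_cluster_template,
    make_docked_complex_fixture,
    make_unit_cell_fixture,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def unit_cell(default_spec):
    return make_unit_cell_fixture(default_spec)


@pytest.fixture(scope="session")
def rod(default_spec, unit_cell):
    asym, operators, cell = unit_cell
    return extract_rod(expand_supercell(asym, operators, default_spec.reps, cell))


@pytest.fixture(scope="session")
def rod_with_clusters(rod):
    sites = detect_cluster_sites(rod)
    return place_clusters(rod, sites, make_cluster_template()), sites


@pytest.fixture(scope="session")
def docked_fixture(default_spec):
    return make_docked_complex_fixture(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
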
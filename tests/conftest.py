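import numpy as np
import pytest

from perchmatch.spaces import build_component_table
from perchmatch.synthgen import DEFAULT_LOCATIONS, EffectSpec, StudyDesign, generate_study
from perchmatch.visionmetrics import ViewerModel


@pytest.fixture(scope="session")
def viewer():
    return ViewerModel()


def small_design(n_per_loc: int = 2, n_corrupted: int = 2) -> StudyDesign:
    locations = {
        loc: (clade, hab, n_per_loc) for loc, (clade, hab, _) in DEFAULT_LOCATIONS.items()
    }
    return StudyDesign(
        n_lizards=n_per_loc * len(locations),
        n_corrupted=n_corrupted,
        locations=locations,
    )


@pytest.fixture(scope="session")
def small_study():
    """14 lizards (2 per location), 2 corrupted backgrounds."""
    return generate_study(small_design(), EffectSpec(), seed=11)


@pytest.fixture(scope="session")
def default_study():
    """The full default design: 52 lizards, 309 usable backgrounds."""
    return generate_study(seed=7)


@pytest.fixture(scope="session")
def small_components(small_study):
    comp, fit = build_component_table(small_study.usable(), n_perm=0, seed=3)
    return comp


@pytest.fixture(scope="session")
def default_components(default_study):
    comp, fit = build_component_table(default_study.usable(), n_perm=0, seed=3)
    return comp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
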
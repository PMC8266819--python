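import numpy as np
import pytest

from hairsimm.chronology import build_chronology
from hairsimm.mixing import MixingSpace, build_mixing_space
from hairsimm.sources import aggregate_all
from hairsimm.synth import (
    ScenarioConfig,
    generate_scenario,
    generate_table1_fixture,
    _samples_from_frame,
)


@pytest.fixture(scope="session")
def table1_samples():
    """Per-sample key-food rows moment-matched to the printed species table."""
    return _samples_from_frame(generate_table1_fixture(seed=0))


@pytest.fixture(scope="session")
def categories(table1_samples):
    return aggregate_all(table1_samples)


@pytest.fixture(scope="session")
def space(categories):
    """The seven-source mixing space with default TEFs (C4 excluded)."""
    return build_mixing_space(categories)


@pytest.fixture(scope="session")
def default_scenario():
    return generate_scenario(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def scenario_sections(default_scenario):
    """Season-assigned, covariate-joined usable sections of the default scenario."""
    ds = default_scenario
    chrono = build_chronology(ds.hairs, ds.sections)
    usable = chrono[chrono["exclusion_reason"] == ""]
    return usable.merge(ds.bears, on="bear_id")


@pytest.fixture
def toy_space():
    """Three well-separated sources with unit concentrations, zero SD."""
    return MixingSpace(
        season=None,
        names=("a", "b", "c"),
        means=np.array([[-30.0, 0.0], [-20.0, 10.0], [-10.0, 0.0]]),
        sds=np.zeros((3, 2)),
        conc=np.ones((3, 2)),
    )
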
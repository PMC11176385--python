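import numpy as np
import pandas as pd
import pytest

from regliab.registry import load_registry
from regliab.simulate import SimulationConfig, make_fixture, simulate_registry


@pytest.fixture(scope="session")
def handcheck_bundle(tmp_path_factory):
    """The four-person hand-enumerable fixture, written and re-loaded."""
    out = tmp_path_factory.mktemp("handcheck")
    truth = make_fixture("tiny_handcheck", out)
    persons, diagnoses = load_registry(out / "persons.tsv", out / "diagnoses.tsv")
    return persons, diagnoses, truth


@pytest.fixture(scope="session")
def moderate_sim():
    """One medium simulated register under the default study conditions."""
    config = SimulationConfig(n_families=30000, seed=424242)
    persons, diagnoses, truth = simulate_registry(config)
    return config, persons, diagnoses, truth
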
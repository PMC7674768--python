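import json
from importlib import resources

import numpy as np
import pytest

from actichain import build_default_chain, RadiobiologyParams
from actichain.fixtures import load_bed_table, load_dose_coefficients


@pytest.fixture(scope="session")
def chain():
    return build_default_chain()


@pytest.fixture(scope="session")
def nuclide_records():
    """Raw packaged nuclide table, read independently of the chain builder."""
    text = resources.files("actichain.data").joinpath("nuclides_ac225.json").read_text()
    return json.loads(text)["nuclides"]


@pytest.fixture(scope="session")
def params():
    return RadiobiologyParams()


@pytest.fixture(scope="session")
def table1():
    return load_dose_coefficients()


@pytest.fixture(scope="session")
def table3():
    return load_bed_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
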
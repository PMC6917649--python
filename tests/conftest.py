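import numpy as np
import pytest

from hopchem.catalog import default_catalog
from hopchem.io import load_table2_fixture, load_table3_fixture
from hopchem.synthetic_data import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def table2():
    """Packaged 30-accession trait table."""
    return load_table2_fixture()


@pytest.fixture(scope="session")
def table3():
    """Packaged flavonol ion catalogue (long format)."""
    return load_table3_fixture()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def default_panel():
    """Default 19+11 panel at a fixed seed."""
    return generate_panel(PanelConfig(seed=11))


def malonyl_proportion_of(truth) -> float:
    la = truth.leaf_abundances
    malonyl = (
        la["kaempferol-3-O-(6''-O-malonyl)-glucoside"]
        + la["quercetin-3-O-(6''-O-malonyl)-glucoside"]
    )
    return malonyl / sum(la.values())
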
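import numpy as np
import pytest

from motudiet import generate_reference_panel, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged two-predator prey-occurrence matrix."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def panel5():
    """Five well-separated mock taxa (>4% between, <2% within)."""
    return generate_reference_panel(5, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
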
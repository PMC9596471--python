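import numpy as np
import pytest

from subnanospec.encode import AB42, Peptide, load_volume_table
from subnanospec.preprocess import znormalize
from subnanospec.theory import theoretical_spectrum, volume_model


@pytest.fixture(scope="session")
def table():
    return load_volume_table()


@pytest.fixture(scope="session")
def ab42():
    return Peptide(AB42, name="AB42")


@pytest.fixture(scope="session")
def ab42_template(ab42, table):
    """Expanded 1AAV volume template of the amyloid-beta fixture, z-normalized."""
    return znormalize(theoretical_spectrum(ab42, volume_model(), table).expanded)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_znormalized(rng, m):
    return znormalize(rng.standard_normal(m))
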
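import numpy as np
import pytest

from ivive import pbtk
from ivive.chem_params import ChemicalRecord
from ivive.dosimetry import KappaCalculator


@pytest.fixture(scope="session")
def phys():
    return pbtk.default_physiology()


@pytest.fixture
def make_chemical():
    counter = {"n": 0}

    def _make(**kwargs):
        counter["n"] += 1
        defaults = dict(
            id=f"TEST{counter['n']:03d}",
            mw=250.0,
            logp=2.0,
            fup=0.3,
            clint_1=5.0,
            loghenry=-7.0,
        )
        defaults.update(kwargs)
        return ChemicalRecord(**defaults)

    return _make


@pytest.fixture
def chem(make_chemical):
    return make_chemical()


@pytest.fixture(scope="session")
def shared_calculator():
    """Session-wide kappa calculator so time courses are reused."""
    return KappaCalculator()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
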
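import numpy as np
import pytest

from coiltools import (ProteinSequence, RandomCoilReference,
                       ResiduePropertyTable, unfolded_im7_variant)


@pytest.fixture(scope="session")
def properties() -> ResiduePropertyTable:
    return ResiduePropertyTable.default()


@pytest.fixture(scope="session")
def coil_reference() -> RandomCoilReference:
    return RandomCoilReference.default()


@pytest.fixture(scope="session")
def variant() -> ProteinSequence:
    """The L18A-L19A-L37A unfolded-state mimic."""
    return unfolded_im7_variant()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
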
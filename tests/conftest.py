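import numpy as np
import pytest

from gsreg import synthetic_data
from gsreg.regulation import default_rules
from gsreg.seq_core import map_reference_positions


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def family():
    """A truth-preserving synthetic family shared across tests."""
    return synthetic_data.make_gs_family(synthetic_data.FamilySpec(seed=11))


@pytest.fixture(scope="session")
def family_pmap(family):
    return map_reference_positions(
        family.msa, family.reference_id, synthetic_data.DIAGNOSTIC_POSITIONS)


#: Residue maps of the two characterized enzymes at the diagnostic positions.
MTGS_RESIDUES = {20: "R", 34: "A", 67: "G", 88: "R", 174: "R", 175: "R", 191: "S"}
MSGS_RESIDUES = {20: "R", 34: "A", 67: "R", 88: "K", 174: "T", 175: "R", 191: "A"}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
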
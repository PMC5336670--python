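import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SMALL_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.000   8.000   9.000  1.00  0.00           C
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.500   2.500   3.500  0.60  0.00           C
ATOM      3  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.000   8.000   9.000  1.00  0.00           C
"""

LIGAND_PDB = """\
HETATM    1  C1  EST L   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  O1  EST L   1       1.230   0.000   0.000  1.00  0.00           O
"""


@pytest.fixture
def small_pdb_text():
    return SMALL_PDB


@pytest.fixture
def altloc_pdb_text():
    return ALTLOC_PDB


@pytest.fixture
def ligand_pdb_text():
    return LIGAND_PDB
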
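import numpy as np
import pytest

from ionprobe import FieldSpec, ligand_schedule

GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      10.729   6.768  -4.123  1.00  0.00           C
ATOM      4  O   GLY A   1       9.700   6.250  -3.500  1.00  0.00           O
ATOM      5  H   GLY A   1      11.600   5.500  -7.100  1.00  0.00           H
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   GLY A   1      10.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1      12.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1      10.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.000   1.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1      12.000   1.000   0.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AGLY A   1      11.639   6.071  -5.147  0.40  0.00           C
ATOM      3  CA BGLY A   1      11.700   6.100  -5.200  0.60  0.00           C
ATOM      4  C   GLY A   1      10.729   6.768  -4.123  1.00  0.00           C
END
"""


@pytest.fixture
def gly_pdb(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(GLY_PDB)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture
def field():
    return FieldSpec(70.966)


@pytest.fixture
def nmr_schedule():
    """A compact titration schedule spanning the millimolar Kd range."""
    return ligand_schedule(P0=1.0, V0=500.0, stock=200.0, additions=[1, 2, 3, 5, 8, 12, 20, 30, 45])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
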
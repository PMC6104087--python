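import numpy as np
import pytest

from dlptether.synthetic import ToySpec, make_tethered_pair


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.031   2.803   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.530   2.605   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.240   3.730   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.693   3.702   0.000  1.00  0.00           C
ATOM      9  C   SER A   3       8.260   5.111   0.000  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA AGLY A   2       3.800   0.000   0.000  0.60  0.00           C
ATOM      3  CA BGLY A   2       3.800   1.000   0.000  0.40  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture(scope="session")
def three_residue_pdb():
    return THREE_RESIDUE_PDB


@pytest.fixture(scope="session")
def altloc_pdb():
    return ALTLOC_PDB


@pytest.fixture(scope="session")
def toy_pair():
    """Default toy tethered system, shared across the session."""
    return make_tethered_pair(ToySpec(seed=0))


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test: data never depends on the
    order in which tests run."""
    return np.random.default_rng(12345)
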
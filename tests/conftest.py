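import numpy as np
import pytest

from trajsim import Trajectory


def random_trajectory(rng, n, scale=1.0, label=""):
    return Trajectory(rng.normal(scale=scale, size=(n, 3)), label=label)


def random_pair(seed, max_len=30, min_len=1):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(min_len, max_len + 1, size=2)
    return random_trajectory(rng, int(n)), random_trajectory(rng, int(m))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# A 2-model PDB of a 3-residue peptide with full backbone atoms, as an
# external structure reader would meet it in the wild.
PDB_3RES_2MODEL = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.021   2.810   0.100  1.00  0.00           C
ATOM      6  C   GLY A   2       5.520   2.700   0.200  1.00  0.00           C
ATOM      7  N   SER A   3       6.230   3.820   0.300  1.00  0.00           N
ATOM      8  CA  SER A   3       7.690   3.880   0.400  1.00  0.00           C
ATOM      9  C   SER A   3       8.270   5.280   0.500  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.109   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.432   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.121   2.810   0.100  1.00  0.00           C
ATOM      6  C   GLY A   2       5.620   2.700   0.200  1.00  0.00           C
ATOM      7  N   SER A   3       6.330   3.820   0.300  1.00  0.00           N
ATOM      8  CA  SER A   3       7.790   3.880   0.400  1.00  0.00           C
ATOM      9  C   SER A   3       8.370   5.280   0.500  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def pdb_3res_2model(tmp_path):
    path = tmp_path / "pep.pdb"
    path.write_text(PDB_3RES_2MODEL)
    return path
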
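import numpy as np
import pandas as pd
import pytest

from sfbench import FeatureTable, SyntheticSpec, gen_dataset

PDB_PROTEIN = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  O   ALA A   1      13.006   6.954  -3.410  1.00  0.00           O
ATOM      4  H   ALA A   1      10.000   6.000  -6.000  1.00  0.00           H
HETATM    5  O   HOH A 101       2.000   2.000   2.000  1.00  0.00           O
END
"""

# single-heavy-atom ligand (methane) for trivial counting tests
MOL2_METHANE = """\
@<TRIPOS>MOLECULE
methane
5 4 0 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1          0.0000    0.0000    0.0000 C.3
      2 H1          0.6300    0.6300    0.6300 H
      3 H2         -0.6300   -0.6300    0.6300 H
      4 H3         -0.6300    0.6300   -0.6300 H
      5 H4          0.6300   -0.6300   -0.6300 H
@<TRIPOS>BOND
     1    1    2 1
     2    1    3 1
     3    1    4 1
     4    1    5 1
"""

PDBQT_LIGAND = """\
ROOT
ATOM      1  C1  LIG A   1       1.000   0.000   0.000  1.00  0.00    0.000 C
ATOM      2  O1  LIG A   1       2.200   0.500   0.000  1.00  0.00   -0.350 OA
ATOM      3  N1  LIG A   1       0.000   1.300   0.500  1.00  0.00   -0.250 NA
ATOM      4  H1  LIG A   1       2.900   0.100   0.300  1.00  0.00    0.200 HD
ATOM      5  B1  LIG A   1      -1.000  -1.000   0.000  1.00  0.00    0.000 B
ENDROOT
TORSDOF 5
"""


@pytest.fixture
def protein_pdb(tmp_path):
    path = tmp_path / "1abc.pdb"
    path.write_text(PDB_PROTEIN)
    return path


@pytest.fixture
def ligand_mol2(tmp_path):
    path = tmp_path / "ligand.mol2"
    path.write_text(MOL2_METHANE)
    return path


@pytest.fixture
def ligand_pdbqt(tmp_path):
    path = tmp_path / "ligand.pdbqt"
    path.write_text(PDBQT_LIGAND)
    return path


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.5, 6.25]],
        index=["1abc", "2xyz"],
        columns=["f1", "f2", "f3"],
    )
    return FeatureTable(df, {"f1": "cyscore", "f2": "vina", "f3": "elem36"})


@pytest.fixture(scope="session")
def linear_dataset():
    """Interaction-free, clustered-noise-free dataset for recovery tests."""
    return gen_dataset(SyntheticSpec(
        n_complexes=150, n_continuous=4, n_counts=2,
        noise_sd=0.0, family_sd=0.0, seed=11,
    ))


@pytest.fixture(scope="session")
def nonadditive_dataset():
    """Strongly non-additive dataset (pairwise interactions on)."""
    from sfbench.synthetic import DEFAULT_INTERACTIONS

    return gen_dataset(SyntheticSpec(
        n_complexes=1000, n_continuous=4, n_counts=16,
        interactions=DEFAULT_INTERACTIONS, family_sd=0.0, seed=21,
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
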
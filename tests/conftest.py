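import numpy as np
import pytest
from hypothesis import settings

from metalloc import probmap, synthdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# fixed-column PDB fixture exercising MODEL/altLoc/water/hydrogen handling
TWO_MODEL_PDB = """\
HEADER    SYNTHETIC FIXTURE
LINK         SG  CYS A   1                ZN    ZN A  90     1555   1555  2.32
LINK         NE2 HIS A   2                ZN    ZN A  90     1555   1555  2.15
LINK         O   HOH A 101                ZN    ZN A  90     1555   1555  2.40
MODEL        1
ATOM      1  N   CYS A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  CYS A   1      10.000   5.500  -5.800  1.00  0.00           C
ATOM      3  CB  CYS A   1       9.000   5.300  -5.300  1.00  0.00           C
ATOM      4  SG ACYS A   1       8.000   5.000  -5.000  0.60  0.00           S
ATOM      5  SG BCYS A   1       8.100   5.100  -5.100  0.40  0.00           S
ATOM      6  H   CYS A   1      11.000   6.000  -6.000  1.00  0.00           H
ATOM      7  N   HIS A   2       7.000   9.000  -2.000  1.00  0.00           N
ATOM      8  CA  HIS A   2       6.500   8.200  -2.600  1.00  0.00           C
ATOM      9  ND1 HIS A   2       5.200   6.400  -3.000  1.00  0.00           N
ATOM     10  NE2 HIS A   2       4.600   5.000  -4.400  1.00  0.00           N
HETATM   11 ZN    ZN A  90       6.000   4.500  -4.200  0.50  0.00          ZN
HETATM   12  O   HOH A 101       3.000   3.000  -3.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   CYS A   1      99.000  99.000  99.000  1.00  0.00           N
ENDMDL
END
"""


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "fixture.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path


@pytest.fixture(scope="session")
def noiseless_protein():
    """Two well-separated noiseless sites (CCCC and CCHH) plus decoys."""
    return synthdata.make_protein(
        [synthdata.SiteSpec("CCCC"), synthdata.SiteSpec("CCHH")],
        n_decoys=12, seed=11)


@pytest.fixture(scope="session")
def training_map():
    """Probability map built from a small balanced synthetic corpus."""
    corpus = synthdata.make_corpus(
        6, ["CCCC", "CCHH", "DHH"], seed=101, noise_sigma=0.1)
    return probmap.build_probability_map([p.structure for p in corpus])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
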
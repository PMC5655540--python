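import math

import numpy as np
import pytest

from ssmflow.library_design import CodingSequence
from ssmflow.ligand_prep import Conformer
from ssmflow.read_processing import ReadPair
from ssmflow._genetics import revcomp

FENTANYL_SMILES = "CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1"


@pytest.fixture(scope="session")
def toy_cds():
    # 10 codons: ATG + 9 sense codons
    return CodingSequence(id="toy", nt="ATGGCTAAACTGGTTGAAGATTTCCGTTGG"[:30])


@pytest.fixture(scope="session")
def fentanyl():
    return Conformer.from_smiles(FENTANYL_SMILES)


@pytest.fixture(scope="session")
def fentanyl_3d():
    """Fentanyl with embedded 3D coordinates (deterministic)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(FENTANYL_SMILES))
    params = AllChem.ETKDGv3()
    params.randomSeed = 0xF00D
    AllChem.EmbedMolecule(mol, params)
    return Conformer.from_rdkit(mol)


@pytest.fixture(scope="session")
def ideal_amine():
    """Tertiary amine with ideal tetrahedral geometry, C-N 1.47 A."""
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1]], dtype=float)
    verts = verts / math.sqrt(3) * 1.47
    atoms = [("N", 0.0, 0.0, 0.0)] + [("C", *v) for v in verts]
    return Conformer(atoms=atoms, bonds=[(0, 1, 1), (0, 2, 1), (0, 3, 1)])


@pytest.fixture(scope="session")
def planar_carbonyl():
    """sp2 carbonyl fragment: C=O of 1.23 A plus two in-plane substituents."""
    atoms = [
        ("C", 0.0, 0.0, 0.0),
        ("O", 1.23, 0.0, 0.0),
        ("C", -0.75, 1.30, 0.0),
        ("C", -0.75, -1.30, 0.0),
    ]
    return Conformer(atoms=atoms, bonds=[(0, 1, 2), (0, 2, 1), (0, 3, 1)])


def random_pair(rng, min_len=15, max_len=50, overlap=None, q=30):
    """Random ReadPair; with ``overlap`` set, build a true overlapping pair."""
    bases = np.array(list("ACGT"))
    if overlap is None:
        lf = int(rng.integers(min_len, max_len + 1))
        lr = int(rng.integers(min_len, max_len + 1))
        fwd = "".join(rng.choice(bases, lf))
        rcr = "".join(rng.choice(bases, lr))
    else:
        lf = int(rng.integers(max(min_len, overlap), max_len + 1))
        lr = int(rng.integers(max(min_len, overlap), max_len + 1))
        template = "".join(rng.choice(bases, lf + lr - overlap))
        fwd = template[:lf]
        rcr = template[-lr:]
    return ReadPair(
        id="r",
        fwd_seq=fwd,
        rev_seq=revcomp(rcr),
        fwd_qual=np.full(len(fwd), q),
        rev_qual=np.full(len(rcr), q),
    )
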
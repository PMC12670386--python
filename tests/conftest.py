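import numpy as np
import pytest

from trajsite.core import Atom, Topology, Trajectory

TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      10.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.000   0.500   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1      12.000   0.000   0.500  1.00  0.00           C
ATOM      4  O   ALA A   1      12.500   1.000   0.500  1.00  0.00           O
ATOM      5  N   GLY A   2      13.000   0.000   1.000  1.00  0.00           N
ATOM      6  CA  GLY A   2      14.000   0.500   1.000  1.00  0.00           C
ATOM      7  C   GLY A   2      15.000   0.000   1.500  1.00  0.00           C
ATOM      8  O   GLY A   2      15.500   1.000   1.500  1.00  0.00           O
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       1.000   2.000   3.000  1.00  0.00           O
HETATM    2  O   HOH A   2       4.000   5.000   6.000  1.00  0.00           O
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "two_residue.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


@pytest.fixture
def water_only_pdb(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(WATER_ONLY_PDB)
    return path


def make_topology(residue_atoms, chain="A"):
    """Build a Topology from [(residue_seq, residue_name, [(atom_name, element), ...]), ...]."""
    atoms = []
    serial = 1
    for seq, res_name, atom_list in residue_atoms:
        for name, element in atom_list:
            atoms.append(Atom(serial=serial, name=name, element=element,
                              residue_seq=seq, residue_name=res_name, chain=chain))
            serial += 1
    return Topology(atoms)


def backbone_residue(seq, res_name="GLY"):
    return (seq, res_name, [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")])


def make_trajectory(topology, frames, dt_ns=0.1):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(topology, frames, dt_ns * np.arange(frames.shape[0]))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
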
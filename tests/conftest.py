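import numpy as np
import pytest

import dfiscan as d


@pytest.fixture(scope="session")
def ring12():
    return d.make_structure("ring", 12)


@pytest.fixture(scope="session")
def chain9():
    return d.make_structure("linear_chain", 9)


@pytest.fixture(scope="session")
def globule30():
    return d.make_structure("globule", 30, seed=3)


@pytest.fixture(scope="session")
def globule50():
    return d.make_structure("globule", 50, seed=5)


@pytest.fixture(scope="session")
def dumbbell43():
    return d.make_structure("dumbbell", 43, seed=0)


def atom_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0, b=0.0,
              altloc=" ", icode=" ", record="ATOM  ", element="C"):
    """One fixed-width PDB ATOM/HETATM record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def pdb_file(tmp_path):
    """Write PDB text lines to a temp file and return the path."""

    def _write(lines, name="toy.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return _write


@pytest.fixture
def three_residue_pdb(pdb_file):
    lines = [
        atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        atom_line(3, "CA", "GLY", "A", 3, 7.6, 0.0, 0.0),
    ]
    return pdb_file(lines)


@pytest.fixture
def analytic_profile():
    """Deterministic profile + structure pair for IO tests."""
    structure = d.make_structure("globule", 12, seed=2)
    res = d.DynamicFlexibilityModel(structure).fit()
    return res.profile, structure
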
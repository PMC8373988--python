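import numpy as np
import pytest

from sanskit.curves import ScatteringCurve

MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.759   7.093  -4.973  1.00 10.00           C
ATOM      4  CA AGLY A   2      13.500   8.000  -3.000  0.40 10.00           C
ATOM      5  CA BGLY A   2      13.600   8.100  -3.100  0.60 10.00           C
HETATM    6  P   AMP A 100       1.000   2.000   3.000  1.00 10.00           P
END
"""

MINI_CIF = """\
data_mini
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA A 1 1 ? 11.104 6.134 -6.504 1.00 10.00 1 A 1
ATOM 2 C CA . ALA A 1 1 ? 11.639 6.071 -5.147 1.00 10.00 1 A 1
ATOM 3 C C . ALA A 1 1 ? 12.759 7.093 -4.973 1.00 10.00 1 A 1
ATOM 4 C CA A GLY A 1 2 ? 13.500 8.000 -3.000 0.40 10.00 2 A 1
ATOM 5 C CA B GLY A 1 2 ? 13.600 8.100 -3.100 0.60 10.00 2 A 1
HETATM 6 P P . AMP B 2 . ? 1.000 2.000 3.000 1.00 10.00 100 A 1
"""


@pytest.fixture
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return str(p)


@pytest.fixture
def mini_cif(tmp_path):
    p = tmp_path / "mini.cif"
    p.write_text(MINI_CIF)
    return str(p)


def guinier_law_curve(i0=2.0, rg=30.0, qmax=0.3, n=300, sigma=1e-3, qmin=0.004):
    q = np.linspace(qmin, qmax, n)
    I = i0 * np.exp(-(rg**2 / 3.0) * q**2)
    return ScatteringCurve(q=q, I=I, sigma=np.full(n, sigma))


@pytest.fixture
def exact_guinier_curve():
    return guinier_law_curve()


def sphere_cloud(rng, n, radius, centre=(0.0, 0.0, 0.0)):
    u = rng.random(n)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return np.asarray(centre) + radius * u[:, None] ** (1.0 / 3.0) * v
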
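"""Shared fixtures: analytic point clouds and tiny text structure files."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from gccd import AlphaCarbonCloud


def distance_matrix(points: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(points, dtype=float)))


@pytest.fixture
def unit_square() -> np.ndarray:
    return np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


@pytest.fixture
def square_cloud_side():
    """Single-chain square cloud of a given side length (consecutive residues)."""

    def make(side: float) -> AlphaCarbonCloud:
        pts = side * np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float
        )
        return AlphaCarbonCloud(
            chain_ids=np.array(["A"] * 4, dtype=object),
            residue_numbers=np.arange(1, 5),
            coords=pts,
        )

    return make


def _pdb_atom(serial, resname, chain, resseq, x, y, z, altloc=" ", occ=1.0,
              name=" CA ", element="C", record="ATOM  "):
    return (
        f"{record}{serial:5d} {name}{altloc}{resname} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Two chains, an altloc pair, and a water that must be excluded."""
    lines = [
        _pdb_atom(1, "PRO", "A", 241, 0.0, 0.0, 0.0),
        _pdb_atom(2, "ALA", "A", 242, 3.8, 0.0, 0.0, altloc="A", occ=0.6),
        _pdb_atom(3, "ALA", "A", 242, 3.9, 0.0, 0.0, altloc="B", occ=0.4),
        _pdb_atom(4, "LEU", "A", 244, 7.6, 0.0, 0.0),
        _pdb_atom(5, "GLY", "B", 241, 0.0, 5.0, 0.0),
        _pdb_atom(6, "SER", "B", 242, 3.8, 5.0, 0.0),
        _pdb_atom(7, "HOH", "A", 301, 9.0, 9.0, 9.0, name=" O  ", element="O",
                  record="HETATM"),
        "END",
        "",
    ]
    path = tmp_path / "two_chain.pdb"
    path.write_text("\n".join(lines))
    return path


@pytest.fixture
def multimodel_pdb(tmp_path):
    """Three frames of a 3-residue chain as MODEL records."""
    lines = []
    for model in range(1, 4):
        lines.append(f"MODEL     {model:4d}")
        for i in range(3):
            lines.append(
                _pdb_atom(i + 1, "ALA", "A", i + 1, 3.8 * i + 0.1 * model, 0.0, 0.0)
            )
        lines.append("ENDMDL")
    lines += ["END", ""]
    path = tmp_path / "traj.pdb"
    path.write_text("\n".join(lines))
    return path


ASSEMBLY_CIF = """\
data_synthetic_dimer
_entry.id synthetic_dimer
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
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
ATOM 1 C CA . ALA A 1 1 1 A 1 0.000 0.000 0.000 1.00 0.00
ATOM 2 C CA . GLY A 1 2 2 A 1 3.800 0.000 0.000 1.00 0.00
#
loop_
_pdbx_struct_assembly.id
_pdbx_struct_assembly.details
_pdbx_struct_assembly.method_details
_pdbx_struct_assembly.oligomeric_details
_pdbx_struct_assembly.oligomeric_count
1 author_defined_assembly ? dimeric 2
#
loop_
_pdbx_struct_assembly_gen.assembly_id
_pdbx_struct_assembly_gen.oper_expression
_pdbx_struct_assembly_gen.asym_id_list
1 '1,2' A
#
loop_
_pdbx_struct_oper_list.id
_pdbx_struct_oper_list.type
_pdbx_struct_oper_list.matrix[1][1]
_pdbx_struct_oper_list.matrix[1][2]
_pdbx_struct_oper_list.matrix[1][3]
_pdbx_struct_oper_list.vector[1]
_pdbx_struct_oper_list.matrix[2][1]
_pdbx_struct_oper_list.matrix[2][2]
_pdbx_struct_oper_list.matrix[2][3]
_pdbx_struct_oper_list.vector[2]
_pdbx_struct_oper_list.matrix[3][1]
_pdbx_struct_oper_list.matrix[3][2]
_pdbx_struct_oper_list.matrix[3][3]
_pdbx_struct_oper_list.vector[3]
1 'identity operation' 1 0 0 0 0 1 0 0 0 0 1 0
2 'crystal symmetry operation' 1 0 0 20 0 1 0 0 0 0 1 0
"""


@pytest.fixture
def assembly_cif(tmp_path):
    """mmCIF whose first assembly is the chain plus a translated copy."""
    path = tmp_path / "dimer.cif"
    path.write_text(ASSEMBLY_CIF)
    return path
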
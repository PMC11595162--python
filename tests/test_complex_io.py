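"""Structure and ligand I/O, protonation, and pocket extraction."""

import numpy as np
import pytest
from rdkit import Chem

from conftest import embedded_mol, graph_mol
from posetriage.complex_io import (
    ProteinLigandComplex,
    ProteinStructure,
    assign_polar_hydrogens,
    extract_pocket,
    read_ligand,
    read_protein,
    write_complex,
    write_protein,
)
from posetriage.errors import ContentError, ContractError, ParseError, StructureError
from posetriage.synthetic_fixtures import FixtureSpec, make_toy_complex


def pdb_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" ",
             element=None, record="ATOM"):
    element = element or name[0]
    return (
        f"{record:<6s}{serial:5d}  {name:<3s}{altloc}{resname:>3s} {chain}{resnum:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture()
def three_residue_pdb(tmp_path):
    """Three glycine backbones (9 atoms), one chain."""
    lines = []
    serial = 1
    for i in range(3):
        x = 3.8 * i
        for name, dx in (("N", 0.0), ("CA", 1.46), ("C", 2.98)):
            lines.append(pdb_line(serial, name, "GLY", "A", i + 1, x + dx, 0.0, 0.0))
            serial += 1
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def test_read_three_residue_fixture(three_residue_pdb):
    st = read_protein(three_residue_pdb)
    assert len(st.atoms) == 9
    assert set(a.chain_id for a in st.atoms) == {"A"}
    assert st.sequences == {"A": "GGG"}


def test_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_line(2, "CA", "GLY", "A", 1, 1.46, 0.0, 0.0, occ=0.6, altloc="A"),
        pdb_line(3, "CA", "GLY", "A", 1, 1.50, 0.3, 0.0, occ=0.4, altloc="B"),
        pdb_line(4, "C", "GLY", "A", 1, 2.98, 0.0, 0.0),
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    st = read_protein(path)
    cas = [a for a in st.atoms if a.name == "CA"]
    assert len(cas) == 1
    assert cas[0].altloc == "A"
    assert cas[0].coords[0] == pytest.approx(1.46, abs=1e-3)


def test_altloc_tie_breaks_lexicographically(tmp_path):
    lines = [
        pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_line(2, "CA", "GLY", "A", 1, 9.0, 0.0, 0.0, occ=0.5, altloc="B"),
        pdb_line(3, "CA", "GLY", "A", 1, 1.46, 0.0, 0.0, occ=0.5, altloc="A"),
        pdb_line(4, "C", "GLY", "A", 1, 2.98, 0.0, 0.0),
    ]
    path = tmp_path / "tie.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    st = read_protein(path)
    ca = [a for a in st.atoms if a.name == "CA"][0]
    assert ca.altloc == "A"


def test_zero_polymer_atoms_is_content_error(tmp_path):
    lines = [pdb_line(1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0, record="HETATM")]
    path = tmp_path / "waters.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    with pytest.raises(ContentError, match="polymer"):
        read_protein(path)


def test_missing_file_is_parse_error(tmp_path):
    with pytest.raises(ParseError):
        read_protein(tmp_path / "nope.pdb")


def test_waters_are_kept_but_flagged(tmp_path, three_residue_pdb):
    text = three_residue_pdb.read_text().replace(
        "END", pdb_line(10, "O", "HOH", "B", 1, 8.0, 8.0, 8.0, record="HETATM") + "\nEND"
    )
    path = tmp_path / "with_water.pdb"
    path.write_text(text)
    st = read_protein(path)
    waters = [a for a in st.atoms if a.residue_name == "HOH"]
    assert len(waters) == 1 and not waters[0].is_polymer
    assert st.sequences == {"A": "GGG"}


def test_protein_roundtrip_preserves_atoms(tmp_path, cage_complex):
    out = tmp_path / "rt.pdb"
    write_protein(cage_complex.protein, out)
    back = read_protein(out)
    orig = cage_complex.protein
    assert len(back.atoms) == len(orig.atoms)
    # PDB groups atoms by residue, so compare per-atom content, not order
    def keyed(st):
        return sorted(st.atoms, key=lambda a: (a.residue_key, a.name))
    assert [a.name for a in keyed(back)] == [a.name for a in keyed(orig)]
    np.testing.assert_allclose(
        np.array([a.coords for a in keyed(back)]),
        np.array([a.coords for a in keyed(orig)]),
        atol=1.5e-3,
    )


def test_read_benzene_sdf(tmp_path):
    lig = embedded_mol("c1ccccc1", "benzene")
    path = tmp_path / "benzene.sdf"
    w = Chem.SDWriter(str(path))
    w.write(lig.mol)
    w.close()
    got = read_ligand(path)
    assert got.n_heavy == 6
    aromatic = [b for b in got.mol.GetBonds() if b.GetIsAromatic()]
    assert len(aromatic) == 6


def test_multi_record_sdf_returns_first_and_reports_rest(tmp_path):
    path = tmp_path / "two.sdf"
    w = Chem.SDWriter(str(path))
    w.write(embedded_mol("c1ccccc1", "first").mol)
    w.write(embedded_mol("CCO", "second").mol)
    w.close()
    with pytest.warns(UserWarning, match="1 additional"):
        got = read_ligand(path)
    assert got.n_heavy == 6
    assert got.extra_records == 1


def test_truncated_sdf_is_parse_error(tmp_path):
    path = tmp_path / "trunc.sdf"
    path.write_text("benzene\n  garbage\n")
    with pytest.raises(ParseError):
        read_ligand(path)


def test_disconnected_ligand_rejected():
    with pytest.raises(StructureError, match="disconnected"):
        graph_mol("CCO.CC")


def test_serine_hydroxyl_gains_one_hydrogen(cage_complex):
    """A serine-like donor (here: the toy ligand's phenol O) gets H at 0.96 A."""
    prot = cage_complex.protein
    # build a serine residue next to the cage and protonate
    from posetriage.complex_io import AtomRecord

    base = np.array([30.0, 0.0, 0.0])
    ser = [
        AtomRecord("N", "N", "SER", 99, "S", base + [0.0, 1.4, 0.0]),
        AtomRecord("C", "CA", "SER", 99, "S", base),
        AtomRecord("C", "C", "SER", 99, "S", base + [1.5, -0.5, 0.0]),
        AtomRecord("O", "O", "SER", 99, "S", base + [2.6, 0.1, 0.0]),
        AtomRecord("C", "CB", "SER", 99, "S", base + [-0.9, -0.7, 1.0]),
        AtomRecord("O", "OG", "SER", 99, "S", base + [-0.9, -0.7, 2.4]),
    ]
    st = ProteinStructure(prot.atoms + ser, source_id="with_ser")
    cplx = ProteinLigandComplex(st, cage_complex.ligand, label="unknown")
    out = assign_polar_hydrogens(cplx)
    og = [a for a in out.protein.atoms if a.name == "OG"][0]
    hs = [a for a in out.protein.atoms
          if a.element == "H" and np.linalg.norm(a.coords - og.coords) < 1.2]
    assert len(hs) == 1
    assert np.linalg.norm(hs[0].coords - og.coords) == pytest.approx(0.96, abs=1e-6)


def test_polar_hydrogen_assignment_is_idempotent(cage_complex):
    once = assign_polar_hydrogens(cage_complex)
    twice = assign_polar_hydrogens(once)
    assert len(twice.protein.atoms) == len(once.protein.atoms)
    np.testing.assert_array_equal(
        np.array([a.coords for a in twice.protein.atoms]),
        np.array([a.coords for a in once.protein.atoms]),
    )
    assert twice.ligand.n_atoms == once.ligand.n_atoms


def test_ligand_carboxylate_deprotonated():
    cplx = make_toy_complex(FixtureSpec(seed=2, ligand_smiles="OC(=O)c1ccc(-c2ccccc2)cc1"))
    out = assign_polar_hydrogens(cplx)
    mol = out.ligand.mol
    charges = [a.GetFormalCharge() for a in mol.GetAtoms() if a.GetSymbol() == "O"]
    assert -1 in charges
    # no H on the carboxylate oxygens
    for a in mol.GetAtoms():
        if a.GetSymbol() == "O" and a.GetFormalCharge() == -1:
            assert a.GetTotalNumHs() == 0


def test_aliphatic_amine_protonated():
    cplx = make_toy_complex(FixtureSpec(seed=2, ligand_smiles="NCCc1ccc(-c2ccccc2)cc1"))
    out = assign_polar_hydrogens(cplx)
    n = [a for a in out.ligand.mol.GetAtoms() if a.GetSymbol() == "N"][0]
    assert n.GetFormalCharge() == 1
    assert n.GetTotalNumHs(includeNeighbors=True) == 3


def test_extract_pocket_monotone_in_radius(cage_complex):
    keys = {}
    for r in (4.0, 6.0, 8.0):
        keys[r] = {res.key for res in extract_pocket(cage_complex, r)}
    assert keys[4.0] <= keys[6.0] <= keys[8.0]


def test_extract_pocket_tiny_radius_errors(cage_complex):
    with pytest.raises(ContentError, match="pocket"):
        extract_pocket(cage_complex, 0.1)
    with pytest.raises(ContractError):
        extract_pocket(cage_complex, -1.0)


def test_extract_pocket_counts_by_distance(cage_complex):
    lig = cage_complex.ligand.coords(heavy_only=True)
    expected = set()
    for res in cage_complex.protein.residues():
        heavy = res.heavy_coords()
        d = np.sqrt(((heavy[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2))
        if (d < 6.0).any():
            expected.add(res.key)
    got = {res.key for res in extract_pocket(cage_complex, 6.0)}
    assert got == expected
    assert len(got) >= 5


def test_write_complex_shares_stem(tmp_path, cage_complex):
    pdb, sdf = write_complex(cage_complex, tmp_path / "pair")
    assert pdb.exists() and sdf.exists()
    assert pdb.stem == sdf.stem
    back = read_ligand(sdf)
    np.testing.assert_allclose(
        back.coords(heavy_only=True),
        cage_complex.ligand.coords(heavy_only=True),
        atol=1.5e-3,
    )


def test_ligand_outside_bounding_box_rejected(cage_complex):
    lig = cage_complex.ligand
    far = lig.with_coords(lig.coords() + 100.0)
    with pytest.raises(ContentError, match="bounding box"):
        ProteinLigandComplex(cage_complex.protein, far, label="unknown")


def test_bad_label_rejected(cage_complex):
    with pytest.raises(ContractError):
        ProteinLigandComplex(cage_complex.protein, cage_complex.ligand, label="maybe")
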
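"""Registry contract, typed interactions, buried-unsat counts, pocket shape,
strain, and featurization invariants."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import embedded_mol
from posetriage.complex_io import (
    AtomRecord,
    LigandMolecule,
    ProteinLigandComplex,
    ProteinStructure,
    assign_polar_hydrogens,
)
from posetriage.errors import ContentError
from posetriage.feature_engine import (
    FeaturizeSettings,
    count_buried_unsat,
    default_registry,
    detect_interactions,
    featurize,
    interface_features,
    ligand_descriptors_2d,
    ligand_strain,
    pocket_shape,
)
from posetriage.synthetic_fixtures import FixtureSpec, make_toy_complex
from rdkit import Chem
from rdkit.Chem import rdMolTransforms
from rdkit.Geometry import Point3D


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def test_registry_holds_166_unique_named_features():
    reg = default_registry()
    assert len(reg) == 166
    assert len(set(reg.names)) == 166
    quotas = {"ligand2d": 40, "ligand_energy": 6, "interface": 60,
              "buried_unsat": 10, "pocket_shape": 20, "burial_misc": 30}
    for family, n in quotas.items():
        assert len(reg.family_names(family)) == n
    assert all(e.description for e in reg.entries)


def test_registry_json_export(tmp_path):
    reg = default_registry()
    path = tmp_path / "registry.json"
    reg.to_json(path)
    import json

    data = json.loads(path.read_text())
    assert data["version"] == reg.version
    assert len(data["entries"]) == 166


# ---------------------------------------------------------------------------
# interactions on constructed geometries
# ---------------------------------------------------------------------------

def _manual_ligand(template_smiles: str, coords: dict[int, np.ndarray], seed=11,
                   name="MAN") -> LigandMolecule:
    """Embedded molecule with selected atom positions overwritten."""
    lig = embedded_mol(template_smiles, name, seed=seed)
    xyz = lig.coords()
    for idx, pos in coords.items():
        xyz[idx] = pos
    return lig.with_coords(xyz)


def _gly_with_amide_h(origin=np.zeros(3)):
    """One glycine whose backbone N carries an explicit hydrogen."""
    n = origin
    h = origin + np.array([1.01, 0.0, 0.0])
    return [
        AtomRecord("N", "N", "GLY", 1, "A", n),
        AtomRecord("H", "H1", "GLY", 1, "A", h),
        AtomRecord("C", "CA", "GLY", 1, "A", origin + [-0.9, 1.1, 0.0]),
        AtomRecord("C", "C", "GLY", 1, "A", origin + [-2.3, 1.0, 0.5]),
        AtomRecord("O", "O", "GLY", 1, "A", origin + [-3.0, 2.0, 0.5]),
    ]


def test_single_hbond_detected_at_constructed_geometry():
    """One N-H...O pair at 2.9 A donor-acceptor distance and a 165 deg angle."""
    protein = ProteinStructure(_gly_with_amide_h(), source_id="donor")
    # acceptor O positioned to give d(N,O) = 2.9 and angle(N,H,O) = 165 deg:
    # H->O makes 15 deg with +x because H->N points along -x
    h = np.array([1.01, 0.0, 0.0])
    direction = np.array([np.cos(np.deg2rad(15)), np.sin(np.deg2rad(15)), 0.0])
    d_ho = 1.912  # law of cosines for d(N,O) = 2.9
    o_pos = h + d_ho * direction
    # acetone: atoms C,C,O,C; put the carbonyl O at o_pos, skeleton behind it
    lig = embedded_mol("CC(C)=O", "ACT")
    o_idx = [a.GetIdx() for a in lig.mol.GetAtoms() if a.GetSymbol() == "O"][0]
    xyz = lig.coords()
    shift = o_pos - xyz[o_idx]
    lig = lig.with_coords(xyz + shift + np.array([0.0, 0.0, 0.0]))
    cplx = ProteinLigandComplex(protein, lig, label="unknown")
    inter = detect_interactions(cplx)
    hbonds = inter.by_type("hbond")
    assert len(hbonds) == 1
    np.testing.assert_allclose(hbonds[0].distance, np.linalg.norm(o_pos), atol=0.05)
    assert hbonds[0].angle >= 120.0


def _detached_complex(cage_complex):
    """Acetone > 8 A outside the cage, toward a bounding-box corner so the
    complex still satisfies the 10 A bounding-margin invariant."""
    prot = cage_complex.protein
    rmax = np.linalg.norm(prot.heavy_coords(), axis=1).max()
    center = (rmax + 10.5) * np.ones(3) / np.sqrt(3.0)
    lig = embedded_mol("CC(C)=O", "FAR")
    lig = lig.with_coords(lig.coords() - lig.coords().mean(axis=0) + center)
    return ProteinLigandComplex(prot, lig, label="unknown")


def test_distant_ligand_yields_empty_interaction_set(cage_complex):
    cplx = _detached_complex(cage_complex)
    with pytest.warns(UserWarning, match="8 A"):
        inter = detect_interactions(cplx)
    assert len(inter) == 0


def _lysine_fragment():
    z = np.array([0.0, 0.0, 1.0])
    atoms = [
        AtomRecord("N", "N", "LYS", 1, "A", -6.0 * z + [1.4, 0, 0]),
        AtomRecord("C", "CA", "LYS", 1, "A", -6.0 * z),
        AtomRecord("C", "C", "LYS", 1, "A", -6.0 * z + [-1.5, 0.3, 0]),
        AtomRecord("O", "O", "LYS", 1, "A", -6.0 * z + [-2.3, -0.6, 0]),
        AtomRecord("C", "CB", "LYS", 1, "A", -4.5 * z),
        AtomRecord("C", "CG", "LYS", 1, "A", -3.0 * z),
        AtomRecord("C", "CD", "LYS", 1, "A", -1.5 * z),
        AtomRecord("C", "CE", "LYS", 1, "A", 0.0 * z),
        AtomRecord("N", "NZ", "LYS", 1, "A", 1.5 * z),
    ]
    return ProteinStructure(atoms, source_id="lys")


def test_salt_bridge_carboxylate_to_lysine():
    """Carboxylate O within 4.0 A of the ammonium N counts as a salt bridge."""
    protein = _lysine_fragment()
    nz = np.array([0.0, 0.0, 1.5])
    lig = embedded_mol("CC(=O)[O-]", "ACE")
    o_minus = [a.GetIdx() for a in lig.mol.GetAtoms() if a.GetFormalCharge() == -1][0]
    xyz = lig.coords()
    target = nz + np.array([0.0, 0.0, 3.5])
    lig = lig.with_coords(xyz + (target - xyz[o_minus]))
    cplx = ProteinLigandComplex(protein, lig, label="unknown")
    inter = detect_interactions(cplx)
    bridges = inter.by_type("salt_bridge")
    assert len(bridges) == 1
    assert bridges[0].distance == pytest.approx(3.5, abs=1e-6)
    assert protein.atoms[bridges[0].protein_atom].name == "NZ"


def _phe_ring(center, z_offset=0.0):
    """PHE side-chain ring (hexagon, radius 1.39 A) plus minimal backbone."""
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = []
    for k, nm in enumerate(names):
        ang = np.pi / 3 * k
        atoms.append(AtomRecord("C", nm, "PHE", 1, "A",
                                center + np.array([1.39 * np.cos(ang),
                                                   1.39 * np.sin(ang), z_offset])))
    atoms += [
        AtomRecord("C", "CB", "PHE", 1, "A", center + [2.9, 0.0, z_offset - 0.5]),
        AtomRecord("C", "CA", "PHE", 1, "A", center + [4.2, 0.6, z_offset - 1.0]),
        AtomRecord("N", "N", "PHE", 1, "A", center + [5.2, -0.3, z_offset - 1.0]),
        AtomRecord("C", "C", "PHE", 1, "A", center + [4.9, 2.0, z_offset - 1.2]),
        AtomRecord("O", "O", "PHE", 1, "A", center + [5.9, 2.7, z_offset - 1.2]),
    ]
    return ProteinStructure(atoms, source_id="phe")


def test_parallel_pi_stack_detected():
    protein = _phe_ring(np.zeros(3))
    benzene = embedded_mol("c1ccccc1", "BNZ")
    xyz = benzene.coords()
    ring_centroid = xyz[: 6].mean(axis=0) if benzene.n_heavy == 6 else xyz.mean(axis=0)
    # move the benzene ring 3.5 A above the PHE ring plane, parallel
    heavy = benzene.coords(heavy_only=True)
    centroid, _, vh = np.linalg.svd(heavy - heavy.mean(axis=0))[0], None, None
    # align benzene plane normal to z by construction: embedded benzene is planar;
    # rotate its normal onto z
    c0 = heavy.mean(axis=0)
    _, _, v = np.linalg.svd(heavy - c0)
    normal = v[2]
    rot = Rotation.align_vectors([[0, 0, 1.0]], [normal])[0].as_matrix()
    moved = (benzene.coords() - c0) @ rot.T + np.array([0.0, 0.0, 3.5])
    benzene = benzene.with_coords(moved)
    cplx = ProteinLigandComplex(protein, benzene, label="unknown")
    inter = detect_interactions(cplx)
    stacks = inter.by_type("pi_stack")
    assert len(stacks) == 1
    assert stacks[0].distance == pytest.approx(3.5, abs=0.05)
    assert stacks[0].angle <= 30.0


def test_contacts_are_deterministically_ordered(cage_complex):
    a = detect_interactions(cage_complex)
    b = detect_interactions(cage_complex)
    assert [(c.type, c.protein_atom, c.ligand_atom) for c in a.contacts] == [
        (c.type, c.protein_atom, c.ligand_atom) for c in b.contacts
    ]
    order = [(c.type, c.protein_atom, c.ligand_atom) for c in a.contacts]
    assert order == sorted(order)


# ---------------------------------------------------------------------------
# buried unsatisfied polar atoms
# ---------------------------------------------------------------------------

def _tight_cage():
    return assign_polar_hydrogens(
        make_toy_complex(FixtureSpec(seed=1, pocket_clearance=2.0))
    )


def test_enclosed_hydroxyl_is_buried_unsatisfied():
    bu = count_buried_unsat(_tight_cage())
    assert bu["bu_donor_O"] == 1
    assert bu["buried_unsat_total"] == 1


def test_partner_at_hbond_geometry_removes_the_count():
    """Satisfaction removes the buried-unsat count and never increases any class."""
    cplx = _tight_cage()
    before = count_buried_unsat(cplx)
    mol = cplx.ligand.mol
    o_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O"][0]
    h_idx = [n.GetIdx() for n in mol.GetAtomWithIdx(o_idx).GetNeighbors()
             if n.GetAtomicNum() == 1][0]
    xyz = cplx.ligand.coords()
    direction = xyz[h_idx] - xyz[o_idx]
    direction /= np.linalg.norm(direction)
    w_pos = xyz[h_idx] + 1.9 * direction
    water = AtomRecord("O", "O", "HOH", 500, "W", w_pos, is_polymer=False)
    st = ProteinStructure(cplx.protein.atoms + [water],
                          sequences=dict(cplx.protein.sequences), source_id="w")
    with_partner = ProteinLigandComplex(st, cplx.ligand, label="active", meta=cplx.meta)
    after = count_buried_unsat(with_partner)
    assert after["buried_unsat_total"] == 0
    assert after["satisfied_buried_count"] == 1
    for key in ("bu_donor_N", "bu_donor_O", "bu_acceptor_N", "bu_acceptor_O", "bu_S"):
        assert after[key] <= before[key]


def test_exposed_hydroxyl_not_buried():
    """A hydroxyl over an open 3-residue surface keeps its solvent exposure."""
    base = [
        a
        for i in range(3)
        for a in _gly_with_amide_h(np.array([4.0 * i, 0.0, -6.0]))
    ]
    # make residue numbers distinct
    atoms = []
    for a in base:
        num = int(round(a.coords[0] / 4.0)) + 1
        atoms.append(AtomRecord(a.element, a.name, a.residue_name, num, "A",
                                a.coords, a.occupancy, a.b_factor, a.altloc, a.is_polymer))
    protein = ProteinStructure(atoms, source_id="flat")
    lig = embedded_mol("Oc1ccc(-c2ccccc2)cc1", "PHL")
    lig = lig.with_coords(lig.coords() - lig.coords(heavy_only=True).mean(axis=0)
                          + np.array([4.0, 0.0, 0.0]))
    cplx = assign_polar_hydrogens(ProteinLigandComplex(protein, lig, label="unknown"))
    bu = count_buried_unsat(cplx)
    assert bu["buried_polar_count"] == 0
    assert bu["buried_unsat_total"] == 0


# ---------------------------------------------------------------------------
# 2D descriptors and strain
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles,expect",
    [
        ("c1ccccc1", {"mol_weight": (78.11, 0.01), "ring_count": (1, 0),
                      "rotatable_bonds": (0, 0), "hbond_donors": (0, 0)}),
        ("CCO", {"hbond_donors": (1, 0), "hbond_acceptors": (1, 0),
                 "rotatable_bonds": (0, 0)}),
        ("c1ccc(-c2ccccc2)cc1", {"rotatable_bonds": (1, 0), "aromatic_ring_count": (2, 0)}),
    ],
)
def test_2d_descriptor_block(smiles, expect):
    block = ligand_descriptors_2d(embedded_mol(smiles))
    for key, (val, tol) in expect.items():
        assert block[key] == pytest.approx(val, abs=max(tol, 1e-9))
    assert len(block) == 40


def test_benzene_strain_is_negligible():
    lig = embedded_mol("c1ccccc1", "BNZ")
    feats = ligand_strain(lig, n_conformers=5, seed=3)
    assert abs(feats["strain_energy"]) < 0.5
    assert feats["ensemble_energy_range"] < 0.5


def test_butane_eclipsed_pose_has_higher_strain():
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles("CCCC"))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    assert AllChem.EmbedMolecule(mol, params) == 0
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)  # H positions stay relaxed
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    conf = mol.GetConformer()
    strains = {}
    for label, angle in (("anti", 180.0), ("eclipsed", 0.0)):
        rdMolTransforms.SetDihedralDeg(conf, *heavy, angle)
        posed = LigandMolecule(Chem.Mol(mol), name=label)  # keep explicit H positions
        strains[label] = ligand_strain(posed, n_conformers=10, seed=3)["strain_energy"]
    assert strains["eclipsed"] > strains["anti"]
    assert strains["eclipsed"] > 2.0  # torsional barrier is kcal/mol scale
    assert abs(strains["anti"]) < 2.0


# ---------------------------------------------------------------------------
# pocket shape
# ---------------------------------------------------------------------------

def test_cage_is_enclosed_bowl_is_open(cage_complex, bowl_complex):
    cage = pocket_shape(cage_complex)
    bowl = pocket_shape(bowl_complex)
    assert cage["enclosure"] >= 0.95
    assert bowl["enclosure"] < cage["enclosure"]
    assert cage["pocket_volume"] > 0
    assert 0.0 < cage["occupied_fraction"] <= 1.0


def test_flat_surface_enclosure_below_half():
    atoms = []
    for i in range(3):
        for a in _gly_with_amide_h(np.array([4.0 * i, 0.0, -5.0])):
            atoms.append(AtomRecord(a.element, a.name, a.residue_name, i + 1, "A",
                                    a.coords))
    protein = ProteinStructure(atoms, source_id="flat3")
    lig = embedded_mol("c1ccccc1", "BNZ")
    lig = lig.with_coords(lig.coords() - lig.coords().mean(axis=0) + np.array([4.0, 0.5, 0.0]))
    cplx = ProteinLigandComplex(protein, lig, label="unknown")
    feats = pocket_shape(cplx)
    assert feats["enclosure"] < 0.5


def test_pocket_volume_grid_convergence(cage_complex):
    coarse = pocket_shape(cage_complex, grid_spacing=0.6)["pocket_volume"]
    fine = pocket_shape(cage_complex, grid_spacing=0.3)["pocket_volume"]
    assert abs(coarse - fine) / fine < 0.10


# ---------------------------------------------------------------------------
# featurize
# ---------------------------------------------------------------------------

def test_featurize_toy_complex_full_vector(cage_complex):
    fv = featurize(cage_complex)
    assert len(fv.values) == 166
    assert fv.n_sentinels == 0
    assert fv.report == {}


def test_featurize_is_bit_stable(cage_complex):
    a = featurize(cage_complex)
    b = featurize(cage_complex)
    assert np.array_equal(a.values, b.values)


def test_family_isolation_on_detached_ligand(cage_complex):
    """A ligand out of pocket range sentinels pocket families only."""
    cplx = _detached_complex(cage_complex)
    fv = featurize(cplx)
    reg = default_registry()
    by_name = dict(zip(fv.names, fv.values))
    assert all(np.isnan(by_name[n]) for n in reg.family_names("pocket_shape"))
    assert "pocket_shape" in fv.report and "burial_misc" in fv.report
    assert not any(np.isnan(by_name[n]) for n in reg.family_names("ligand2d"))
    assert not any(np.isnan(by_name[n]) for n in reg.family_names("interface"))


def test_features_invariant_under_rigid_transform(cage_complex):
    """A joint rotation + translation changes no feature beyond 1e-6 relative."""
    rot = Rotation.from_euler("xyz", [31, -47, 112], degrees=True).as_matrix()
    shift = np.array([5.0, -3.0, 8.0])
    prot = cage_complex.protein
    moved_atoms = [
        AtomRecord(a.element, a.name, a.residue_name, a.residue_number, a.chain_id,
                   rot @ a.coords + shift, a.occupancy, a.b_factor, a.altloc, a.is_polymer)
        for a in prot.atoms
    ]
    protein2 = ProteinStructure(moved_atoms, sequences=dict(prot.sequences),
                                source_id=prot.source_id)
    ligand2 = cage_complex.ligand.with_coords(cage_complex.ligand.coords() @ rot.T + shift)
    moved = ProteinLigandComplex(protein2, ligand2, label=cage_complex.label,
                                 complex_id=cage_complex.complex_id, meta=cage_complex.meta)
    a = featurize(cage_complex)
    b = featurize(moved)
    rel = np.abs(a.values - b.values) / np.maximum(1e-9, np.abs(a.values))
    assert rel.max() < 1e-6


def test_interface_block_counts_match_interactions(cage_complex):
    inter = detect_interactions(cage_complex)
    feats = interface_features(cage_complex, inter)
    total = sum(feats[f"{t}_count"] for t in
                ("hbond", "hydrophobic", "salt_bridge", "pi_stack",
                 "cation_pi", "halogen_bond"))
    assert feats["total_contact_count"] == total == len(inter)
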
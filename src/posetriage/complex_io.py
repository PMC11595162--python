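"""Protein structures, ligand poses, and the protein-ligand complex model.

Proteins are read from PDB/mmCIF via gemmi and held as a flat list of
:class:`AtomRecord`; ligands are read from SDF/MOL2 via RDKit and wrapped in
:class:`LigandMolecule`.  A :class:`ProteinLigandComplex` binds one protein
and one ligand pose in a shared Cartesian frame and is the unit every
downstream feature is computed on.

Alternate locations are collapsed to a single conformer: the highest
occupancy wins, ties go to the lexicographically first altloc tag.  Waters
and non-target heteroatoms are retained (flagged ``is_polymer=False``) but
excluded from the polymer sequence; feature code decides their use
explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import ContentError, ContractError, ParseError, StructureError

RDLogger.DisableLog("rdApp.*")

STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_KNOWN_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu",
    "Zn", "Se", "Br", "I", "Mo", "W", "Cd", "Hg", "Mg",
}


@dataclass
class AtomRecord:
    """One atom of a protein structure, coordinates in Angstrom."""

    element: str
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    is_polymer: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ContractError(f"non-finite coordinates for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ContractError(f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}")
        if self.element.capitalize() not in _KNOWN_ELEMENTS:
            raise ContractError(f"unrecognized element symbol {self.element!r}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)


@dataclass
class Residue:
    """A group of atoms sharing (chain, number, name)."""

    chain_id: str
    number: int
    name: str
    atoms: list[AtomRecord]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.name)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.element != "H"]
        return np.array(pts) if pts else np.zeros((0, 3))


@dataclass
class ProteinStructure:
    """A protein model: ordered atoms plus per-chain one-letter sequences."""

    atoms: list[AtomRecord]
    sequences: dict[str, str] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            self.sequences = self._derive_sequences()
        if not any(self.sequences.values()):
            raise ContentError(f"structure {self.source_id!r} has no polymer chain")
        for chain, seq in self.sequences.items():
            n_ca = sum(
                1 for a in self.atoms if a.is_polymer and a.chain_id == chain and a.name == "CA"
            )
            if len(seq) != n_ca:
                raise ContentError(
                    f"chain {chain}: sequence length {len(seq)} != CA count {n_ca}"
                )

    def _derive_sequences(self) -> dict[str, str]:
        seqs: dict[str, list[str]] = {}
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if not a.is_polymer or a.name != "CA":
                continue
            if a.residue_key in seen:
                continue
            seen.add(a.residue_key)
            seqs.setdefault(a.chain_id, []).append(STANDARD_AA.get(a.residue_name, "X"))
        return {c: "".join(s) for c, s in seqs.items()}

    def residues(self, polymer_only: bool = True) -> list[Residue]:
        groups: dict[tuple[str, int, str], Residue] = {}
        for a in self.atoms:
            if polymer_only and not a.is_polymer:
                continue
            if a.residue_key not in groups:
                groups[a.residue_key] = Residue(a.chain_id, a.residue_number, a.residue_name, [])
            groups[a.residue_key].atoms.append(a)
        return list(groups.values())

    def heavy_coords(self, polymer_only: bool = False) -> np.ndarray:
        pts = [
            a.coords
            for a in self.atoms
            if a.element != "H" and (a.is_polymer or not polymer_only)
        ]
        return np.array(pts) if pts else np.zeros((0, 3))


class LigandMolecule:
    """A small molecule (graph + optional 3D pose), backed by an RDKit Mol.

    The heavy-atom graph must be connected; bond orders and formal charges
    are preserved from the source connection table.
    """

    def __init__(self, mol: Chem.Mol, name: str = "", extra_records: int = 0):
        if mol is None:
            raise StructureError("ligand molecule is None")
        frags = Chem.GetMolFrags(mol)
        if len(frags) > 1:
            raise StructureError(f"ligand heavy-atom graph is disconnected ({len(frags)} fragments)")
        self.mol = mol
        self.name = name or (mol.GetProp("_Name") if mol.HasProp("_Name") else "LIG")
        self.extra_records = extra_records
        if mol.GetNumConformers() > 0:
            xyz = self.coords()
            if not np.all(np.isfinite(xyz)):
                raise StructureError("ligand pose has non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def n_heavy(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def has_pose(self) -> bool:
        return self.mol.GetNumConformers() > 0

    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    def formal_charges(self) -> list[int]:
        return [a.GetFormalCharge() for a in self.mol.GetAtoms()]

    def bonds(self) -> list[tuple[int, int, float]]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        if not self.has_pose:
            raise ContentError(f"ligand {self.name} has no 3D pose")
        conf = self.mol.GetConformer()
        xyz = conf.GetPositions()
        if heavy_only:
            mask = [a.GetAtomicNum() > 1 for a in self.mol.GetAtoms()]
            xyz = xyz[np.array(mask)]
        return np.asarray(xyz, dtype=float)

    def with_coords(self, xyz: np.ndarray, name: str | None = None) -> "LigandMolecule":
        """Copy of this molecule with replaced atom coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ContractError(f"coordinate array shape {xyz.shape} != ({self.n_atoms}, 3)")
        mol = Chem.Mol(self.mol)
        if mol.GetNumConformers() == 0:
            conf = Chem.Conformer(mol.GetNumAtoms())
            mol.AddConformer(conf, assignId=True)
        conf = mol.GetConformer()
        for i in range(self.n_atoms):
            conf.SetAtomPosition(i, xyz[i].tolist())
        return LigandMolecule(mol, name=name or self.name)

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.mol))


@dataclass
class ProteinLigandComplex:
    """One protein plus one ligand pose; the unit features are computed on."""

    protein: ProteinStructure
    ligand: LigandMolecule
    label: str = "unknown"
    copy_index: int = 0
    complex_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("active", "decoy", "unknown"):
            raise ContractError(f"label must be active/decoy/unknown, got {self.label!r}")
        if not self.complex_id:
            self.complex_id = f"{self.protein.source_id or 'complex'}_{self.ligand.name}_{self.copy_index}"
        if self.ligand.has_pose:
            prot = self.protein.heavy_coords()
            lig = self.ligand.coords(heavy_only=True)
            lo = prot.min(axis=0) - 10.0
            hi = prot.max(axis=0) + 10.0
            if np.any(lig < lo) or np.any(lig > hi):
                raise ContentError(
                    "ligand heavy atoms fall outside the protein bounding box expanded by 10 A"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_protein_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_protein(path: str | Path, format: str | None = None) -> ProteinStructure:
    """Read a protein structure from PDB or mmCIF.

    All ATOM/HETATM records are represented; waters are kept but flagged as
    non-polymer; alternate locations are collapsed (highest occupancy, ties
    to the first tag).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or _infer_protein_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise ContractError(f"unknown protein format {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name} as {fmt}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ContentError(f"{path.name}: no models")

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            is_poly = res.name in STANDARD_AA
            # collapse altlocs: group by atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, alts in by_name.items():
                best = sorted(alts, key=lambda a: (-a.occ, a.altloc or ""))[0]
                atoms.append(
                    AtomRecord(
                        element=best.element.name,
                        name=name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        coords=np.array([best.pos.x, best.pos.y, best.pos.z]),
                        occupancy=min(max(best.occ, 0.0), 1.0),
                        b_factor=best.b_iso,
                        altloc=best.altloc or "",
                        is_polymer=is_poly,
                    )
                )
    if not any(a.is_polymer for a in atoms):
        raise ContentError(f"{path.name}: zero polymer atoms")
    return ProteinStructure(atoms=atoms, source_id=path.stem)


def write_protein(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure as PDB (coordinates to 3 decimals, PDB v3.3 columns)."""
    # gemmi's add_* methods copy their argument, so build bottom-up:
    # finish each residue before adding it to its chain, each chain before
    # adding it to the model.
    by_chain: dict[str, dict[tuple[str, int, str], list[AtomRecord]]] = {}
    for a in structure.atoms:
        by_chain.setdefault(a.chain_id, {}).setdefault(a.residue_key, []).append(a)

    st = gemmi.Structure()
    st.name = structure.source_id or "model"
    model = gemmi.Model("1")
    for chain_id, residues in by_chain.items():
        chain = gemmi.Chain(chain_id)
        for key, atoms in residues.items():
            res = gemmi.Residue()
            res.name = key[2]
            res.seqid = gemmi.SeqId(key[1], " ")
            res.het_flag = "A" if atoms[0].is_polymer else "H"
            for a in atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coords)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                if a.altloc:
                    atom.altloc = a.altloc
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def read_ligand(path: str | Path, format: str | None = None) -> LigandMolecule:
    """Read a ligand from SDF (V2000) or MOL2; first record wins.

    If an SDF holds several records, the first is returned and the number of
    remaining records is reported on ``extra_records`` (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or ("mol2" if path.suffix.lower() == ".mol2" else "sdf")
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        raw = [m for m in supplier]
        if not raw or raw[0] is None:
            raise ParseError(f"cannot parse first SDF record in {path.name}")
        mol = raw[0]
        extra = len(raw) - 1
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise ParseError(f"cannot parse {path.name} as MOL2")
        extra = 0
    else:
        raise ContractError(f"unknown ligand format {fmt!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types here
        raise StructureError(f"{path.name}: inconsistent valence/aromaticity: {exc}") from exc
    if extra:
        warnings.warn(f"{path.name}: {extra} additional record(s) ignored", stacklevel=2)
    return LigandMolecule(mol, extra_records=extra)


def write_ligand(ligand: LigandMolecule, path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    mol = Chem.Mol(ligand.mol)
    mol.SetProp("_Name", ligand.name)
    writer.write(mol)
    writer.close()


def write_complex(cplx: ProteinLigandComplex, stem: str | Path) -> tuple[Path, Path]:
    """Write a complex as ``<stem>.pdb`` + ``<stem>.sdf`` (shared stem)."""
    stem = Path(stem)
    pdb_path = stem.with_suffix(".pdb")
    sdf_path = stem.with_suffix(".sdf")
    write_protein(cplx.protein, pdb_path)
    write_ligand(cplx.ligand, sdf_path)
    return pdb_path, sdf_path


# ---------------------------------------------------------------------------
# polar hydrogen assignment
# ---------------------------------------------------------------------------

#: Side-chain donor templates: residue -> donor atom -> (heavy neighbours, n_H, X-H length)
_DONOR_TEMPLATES: dict[str, dict[str, tuple[tuple[str, ...], int, float]]] = {
    "SER": {"OG": (("CB",), 1, 0.96)},
    "THR": {"OG1": (("CB",), 1, 0.96)},
    "TYR": {"OH": (("CZ",), 1, 0.96)},
    "CYS": {"SG": (("CB",), 1, 1.34)},
    "LYS": {"NZ": (("CE",), 3, 1.01)},
    "ARG": {
        "NE": (("CD", "CZ"), 1, 1.01),
        "NH1": (("CZ",), 2, 1.01),
        "NH2": (("CZ",), 2, 1.01),
    },
    "HIS": {"NE2": (("CD2", "CE1"), 1, 1.01)},
    "ASN": {"ND2": (("CG",), 2, 1.01)},
    "GLN": {"NE2": (("CD",), 2, 1.01)},
    "TRP": {"NE1": (("CD1", "CE1"), 1, 1.01)},
}

_NH_LENGTH = 1.01


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise NumericError("zero-length direction vector")
    return v / n


def _perpendicular(v: np.ndarray) -> np.ndarray:
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(v)))] = 1.0
    return _unit(np.cross(v, axis))


@dataclass
class ProtonationReport:
    """Counts of hydrogens added/skipped during polar-H assignment."""

    added_protein: int = 0
    added_ligand: int = 0
    skipped: list[str] = field(default_factory=list)
    ligand_rules_applied: list[str] = field(default_factory=list)


def _has_hydrogen_near(donor: AtomRecord, residue: Residue) -> bool:
    for a in residue.atoms:
        if a.element == "H" and np.linalg.norm(a.coords - donor.coords) < 1.25:
            return True
    return False


def _place_hydrogens(
    donor: AtomRecord, neighbors: list[np.ndarray], n_h: int, length: float,
    anti_ref: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Idealized H positions for a donor given its bonded heavy neighbours.

    Two neighbours (sp2 N-H): H along the external bisector.  One neighbour:
    a single H is placed at the tetrahedral/anti direction (anti to
    ``anti_ref`` when given, else along the bond); two H at +-120 deg in a
    deterministic plane; three H as a staggered tetrahedral tripod.
    """
    d = donor.coords
    if len(neighbors) >= 2:
        direction = _unit(_unit(d - neighbors[0]) + _unit(d - neighbors[1]))
        return [d + length * direction]
    axis = _unit(d - neighbors[0])
    if n_h == 1:
        if anti_ref is not None:
            # tetrahedral: in the plane of (anti_ref, neighbour, donor), 109.5 deg from the bond
            in_plane = _unit(neighbors[0] - anti_ref)
            perp = in_plane - np.dot(in_plane, axis) * axis
            perp = _perpendicular(axis) if np.linalg.norm(perp) < 1e-6 else _unit(perp)
            tilt = np.pi - np.deg2rad(109.5)
            direction = _unit(np.cos(tilt) * axis + np.sin(tilt) * perp)
            return [d + length * direction]
        return [d + length * axis]
    perp = _perpendicular(axis)
    perp2 = np.cross(axis, perp)
    if n_h == 2:
        # sp2 NH2: both H in plane, 120 deg from the heavy bond
        ang = np.deg2rad(120.0)
        out: list[np.ndarray] = []
        for sign in (+1.0, -1.0):
            direction = _unit(np.cos(np.pi - ang) * (-axis) + sign * np.sin(np.pi - ang) * perp)
            out.append(d + length * direction)
        return out
    # sp3 tripod (e.g. lysine NZ): 109.5 deg from the bond, 120 deg apart
    ang = np.deg2rad(109.5)
    out = []
    for k in range(3):
        phi = 2.0 * np.pi * k / 3.0
        lateral = np.cos(phi) * perp + np.sin(phi) * perp2
        direction = _unit(np.cos(np.pi - ang) * (-axis) + np.sin(np.pi - ang) * lateral)
        out.append(d + length * direction)
    return out


def _protonate_protein(protein: ProteinStructure, report: ProtonationReport) -> ProteinStructure:
    new_atoms = list(protein.atoms)
    residues = protein.residues(polymer_only=True)
    by_key = {r.key: r for r in residues}
    # previous-residue C lookup for backbone amides
    ordered = sorted(by_key, key=lambda k: (k[0], k[1]))
    prev_of: dict[tuple[str, int, str], tuple[str, int, str] | None] = {}
    for i, key in enumerate(ordered):
        prev = ordered[i - 1] if i > 0 and ordered[i - 1][0] == key[0] and ordered[i - 1][1] == key[1] - 1 else None
        prev_of[key] = prev

    def add_h(donor: AtomRecord, positions: Iterable[np.ndarray], base: str) -> None:
        for j, pos in enumerate(positions):
            new_atoms.append(
                AtomRecord(
                    element="H",
                    name=f"{base}{j + 1}",
                    residue_name=donor.residue_name,
                    residue_number=donor.residue_number,
                    chain_id=donor.chain_id,
                    coords=pos,
                    occupancy=1.0,
                    is_polymer=donor.is_polymer,
                )
            )
            report.added_protein += 1

    for res in residues:
        # backbone amide N-H
        n_at = res.atom("N")
        if n_at is not None and res.name != "PRO" and not _has_hydrogen_near(n_at, res):
            ca = res.atom("CA")
            prev_key = prev_of.get(res.key)
            c_prev = by_key[prev_key].atom("C") if prev_key else None
            if ca is not None and c_prev is not None:
                pos = _place_hydrogens(n_at, [ca.coords, c_prev.coords], 1, _NH_LENGTH)
                add_h(n_at, pos, "H")
            else:
                report.skipped.append(f"{res.chain_id}{res.number}:{res.name}:N")
        # side-chain donors
        for atom_name, (nbr_names, n_h, length) in _DONOR_TEMPLATES.get(res.name, {}).items():
            donor = res.atom(atom_name)
            if donor is None:
                continue
            if _has_hydrogen_near(donor, res):
                continue
            nbrs = [res.atom(n) for n in nbr_names]
            nbrs = [a.coords for a in nbrs if a is not None]
            if not nbrs:
                report.skipped.append(f"{res.chain_id}{res.number}:{res.name}:{atom_name}")
                continue
            anti_ref = None
            if len(nbr_names) == 1 and n_h == 1:
                # hydroxyl / thiol: orient anti to the neighbour's own neighbour
                anchor = {"OG": "CA", "OG1": "CA", "OH": "CE1", "SG": "CA"}.get(atom_name)
                anchor_at = res.atom(anchor) if anchor else None
                anti_ref = anchor_at.coords if anchor_at is not None else None
            pos = _place_hydrogens(donor, nbrs, n_h, length, anti_ref=anti_ref)
            add_h(donor, pos, f"H{atom_name}")
    return ProteinStructure(new_atoms, sequences=dict(protein.sequences), source_id=protein.source_id)


_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_ALIPHATIC_AMINE = Chem.MolFromSmarts("[NX3;H2,H1,H0;+0;!$(N~[!#6;!#1]);!$(NC=[O,N,S]);!$(Na)]")


def _protonate_ligand(ligand: LigandMolecule, report: ProtonationReport) -> LigandMolecule:
    """Rule-based (pKa-free) ligand protonation.

    Carboxylic acids are deprotonated (-1); aliphatic amines are protonated
    (+1); explicit polar hydrogens are then added with coordinates.
    """
    mol = Chem.RWMol(Chem.Mol(ligand.mol))
    for match in mol.GetSubstructMatches(_CARBOXYLIC_ACID):
        o = mol.GetAtomWithIdx(match[2])
        if o.GetFormalCharge() == 0:
            o.SetFormalCharge(-1)
            o.SetNumExplicitHs(0)
            o.SetNoImplicit(True)
            report.ligand_rules_applied.append("carboxylate_deprotonated")
    for match in mol.GetSubstructMatches(_ALIPHATIC_AMINE):
        n = mol.GetAtomWithIdx(match[0])
        if n.GetTotalDegree() >= 4 and n.GetTotalNumHs(includeNeighbors=True) == 0:
            continue
        if not n.GetIsAromatic() and n.GetFormalCharge() == 0:
            n.SetFormalCharge(1)
            n.SetNumExplicitHs(n.GetTotalNumHs(includeNeighbors=True) + 1)
            report.ligand_rules_applied.append("amine_protonated")
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    polar_idx = [
        a.GetIdx()
        for a in out.GetAtoms()
        if a.GetSymbol() in ("N", "O", "S") and a.GetTotalNumHs(includeNeighbors=True) > 0
    ]
    n_before = out.GetNumAtoms()
    if polar_idx:
        out = Chem.AddHs(out, addCoords=ligand.has_pose, onlyOnAtoms=polar_idx)
    report.added_ligand += out.GetNumAtoms() - n_before
    return LigandMolecule(out, name=ligand.name)


def assign_polar_hydrogens(cplx: ProteinLigandComplex) -> ProteinLigandComplex:
    """Add explicit polar hydrogens to protein donors and the ligand.

    Deterministic and idempotent: donors that already carry a hydrogen are
    left untouched.  Hydrogens that cannot be placed (missing bonded heavy
    neighbour) are skipped with a warning and counted in the report attached
    at ``meta['protonation']``.
    """
    report = ProtonationReport()
    protein = _protonate_protein(cplx.protein, report)
    ligand = _protonate_ligand(cplx.ligand, report)
    if report.skipped:
        warnings.warn(
            f"{len(report.skipped)} polar hydrogen(s) skipped (missing neighbours)",
            stacklevel=2,
        )
    meta = dict(cplx.meta)
    meta["protonation"] = report
    return ProteinLigandComplex(
        protein=protein,
        ligand=ligand,
        label=cplx.label,
        copy_index=cplx.copy_index,
        complex_id=cplx.complex_id,
        meta=meta,
    )


def extract_pocket(cplx: ProteinLigandComplex, radius: float) -> list[Residue]:
    """Polymer residues with >= 1 heavy atom within ``radius`` of any ligand heavy atom."""
    if radius <= 0:
        raise ContractError("pocket radius must be positive")
    lig = cplx.ligand.coords(heavy_only=True)
    pocket: list[Residue] = []
    for res in cplx.protein.residues(polymer_only=True):
        heavy = res.heavy_coords()
        if heavy.size == 0:
            continue
        d2 = ((heavy[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        if (d2 < radius * radius).any():
            pocket.append(res)
    if not pocket:
        raise ContentError(f"empty pocket at radius {radius} A (ligand not in contact)")
    return pocket
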
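"""The per-complex descriptor set: 166 named features in six families.

Families and quotas (documented; the count, not the precise identity, is the
registry's contract):

* ``ligand2d`` (40)      - graph/topology descriptors of the ligand alone
* ``ligand_energy`` (6)  - MMFF94 pose energy and conformational strain
* ``interface`` (60)     - typed protein-ligand contacts and contact geometry
* ``buried_unsat`` (10)  - buried-unsatisfied polar group counts
* ``pocket_shape`` (20)  - grid/ray measures of pocket geometry
* ``burial_misc`` (30)   - SASA partitions and burial fractions

Every feature is invariant under a joint rigid transform of protein and
ligand: all geometric quantities are built from interatomic distances,
areas, volumes, or from rays expressed in a canonical frame derived from
the ligand's own principal axes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, GraphDescriptors, QED, rdMolDescriptors
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .complex_io import ProteinLigandComplex, Residue, assign_polar_hydrogens, extract_pocket
from .errors import ContentError, ContractError
from .geometry import (
    DEFAULT_PROBE,
    DEFAULT_SASA_POINTS,
    SASAResult,
    compute_sasa,
    fibonacci_sphere,
    vdw_radius,
)

REGISTRY_VERSION = "1.0"
SENTINEL = float("nan")

RESIDUE_TYPES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

CONTACT_TYPES = ["hbond", "hydrophobic", "salt_bridge", "pi_stack", "cation_pi", "halogen_bond"]


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureEntry:
    name: str
    family: str
    units: str
    description: str


@dataclass
class FeatureRegistry:
    """The ordered, versioned list of descriptor definitions."""

    entries: list[FeatureEntry]
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ContractError("feature names must be unique")
        if len(names) != 166:
            raise ContractError(f"registry must hold exactly 166 features, got {len(names)}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def family_names(self, family: str) -> list[str]:
        return [e.name for e in self.entries if e.family == family]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "version": self.version,
                "entries": [
                    {"name": e.name, "family": e.family, "units": e.units,
                     "description": e.description}
                    for e in self.entries
                ],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _ligand2d_entries() -> list[FeatureEntry]:
    f = lambda n, u, d: FeatureEntry(n, "ligand2d", u, d)
    return [
        f("mol_weight", "Da", "molecular weight"),
        f("heavy_atom_count", "count", "non-hydrogen atoms"),
        f("ring_count", "count", "SSSR ring count"),
        f("aromatic_ring_count", "count", "aromatic rings"),
        f("aliphatic_ring_count", "count", "non-aromatic rings"),
        f("saturated_ring_count", "count", "fully saturated rings"),
        f("heterocycle_count", "count", "rings containing a heteroatom"),
        f("aromatic_heterocycle_count", "count", "aromatic heterocycles"),
        f("largest_ring_size", "count", "size of the largest SSSR ring"),
        f("rotatable_bonds", "count", "strict rotatable bonds (terminal and ring bonds excluded)"),
        f("hbond_donors", "count", "H-bond donor groups"),
        f("hbond_acceptors", "count", "H-bond acceptor groups"),
        f("tpsa", "A^2", "topological polar surface area"),
        f("clogp", "dimensionless", "Wildman-Crippen logP estimate"),
        f("molar_refractivity", "dimensionless", "Wildman-Crippen molar refractivity"),
        f("formal_charge", "e", "net formal charge"),
        f("fraction_csp3", "dimensionless", "fraction of sp3 carbons"),
        f("stereocenters", "count", "assigned + unassigned tetrahedral stereocenters"),
        f("unspecified_stereocenters", "count", "unassigned stereocenters"),
        f("amide_bond_count", "count", "amide bonds"),
        f("spiro_atom_count", "count", "spiro ring-fusion atoms"),
        f("bridgehead_atom_count", "count", "bridgehead atoms"),
        f("carbon_count", "count", "carbon atoms"),
        f("nitrogen_count", "count", "nitrogen atoms"),
        f("oxygen_count", "count", "oxygen atoms"),
        f("sulfur_count", "count", "sulfur atoms"),
        f("halogen_count", "count", "F/Cl/Br/I atoms"),
        f("phosphorus_count", "count", "phosphorus atoms"),
        f("balaban_j", "dimensionless", "Balaban J connectivity index"),
        f("bertz_ct", "dimensionless", "Bertz molecular complexity"),
        f("chi0v", "dimensionless", "valence connectivity chi-0v"),
        f("chi1v", "dimensionless", "valence connectivity chi-1v"),
        f("chi2v", "dimensionless", "valence connectivity chi-2v"),
        f("chi3v", "dimensionless", "valence connectivity chi-3v"),
        f("kappa1", "dimensionless", "Kier shape index kappa-1"),
        f("kappa2", "dimensionless", "Kier shape index kappa-2"),
        f("kappa3", "dimensionless", "Kier shape index kappa-3"),
        f("hall_kier_alpha", "dimensionless", "Hall-Kier alpha"),
        f("labute_asa", "A^2", "Labute approximate surface area"),
        f("qed", "dimensionless", "quantitative estimate of drug-likeness"),
    ]


def _ligand_energy_entries() -> list[FeatureEntry]:
    f = lambda n, d: FeatureEntry(n, "ligand_energy", "kcal/mol", d)
    return [
        f("pose_energy", "MMFF94 energy of the bound pose"),
        f("ensemble_min_energy", "minimum MMFF94 energy over a conformer ensemble"),
        f("strain_energy", "pose energy minus ensemble minimum (>= 0 up to tolerance)"),
        FeatureEntry("strain_per_heavy_atom", "ligand_energy", "kcal/mol", "strain / heavy atoms"),
        FeatureEntry("strain_per_rotor", "ligand_energy", "kcal/mol",
                     "strain / (1 + rotatable bonds)"),
        f("ensemble_energy_range", "max - min energy within the relaxed ensemble"),
    ]


def _interface_entries() -> list[FeatureEntry]:
    out: list[FeatureEntry] = []
    for t in CONTACT_TYPES:
        out.append(FeatureEntry(f"{t}_count", "interface", "count", f"{t} contacts"))
        out.append(FeatureEntry(f"{t}_min_distance", "interface", "A",
                                f"shortest {t} contact distance (0 if none)"))
        out.append(FeatureEntry(f"{t}_mean_distance", "interface", "A",
                                f"mean {t} contact distance (0 if none)"))
    out.append(FeatureEntry("hbond_ligand_donor_count", "interface", "count",
                            "H-bonds donated by the ligand"))
    out.append(FeatureEntry("hbond_protein_donor_count", "interface", "count",
                            "H-bonds donated by the protein"))
    for res in RESIDUE_TYPES:
        out.append(FeatureEntry(f"contacts_res_{res}", "interface", "count",
                                f"contacts involving {res} residues"))
    for el in ["C", "N", "O", "S", "halogen"]:
        out.append(FeatureEntry(f"contacts_lig_{el}", "interface", "count",
                                f"contacts through ligand {el} atoms"))
    edges = np.arange(2.5, 7.0, 0.5)
    for lo in edges:
        out.append(FeatureEntry(f"heavy_pairs_{lo:.1f}_{lo + 0.5:.1f}", "interface", "count",
                                f"protein-ligand heavy atom pairs in [{lo:.1f}, {lo + 0.5:.1f}) A"))
    out += [
        FeatureEntry("total_contact_count", "interface", "count", "all typed contacts"),
        FeatureEntry("contact_density", "interface", "count",
                     "typed contacts per ligand heavy atom"),
        FeatureEntry("n_contact_residues", "interface", "count",
                     "distinct residues involved in contacts"),
        FeatureEntry("hbond_mean_angle", "interface", "deg",
                     "mean D-H...A angle over H-bonds (0 if none)"),
        FeatureEntry("min_heavy_atom_distance", "interface", "A",
                     "closest protein-ligand heavy atom approach"),
        FeatureEntry("polar_contact_fraction", "interface", "dimensionless",
                     "(hbond + salt bridge) / all contacts (0 if none)"),
    ]
    return out


def _buried_unsat_entries() -> list[FeatureEntry]:
    f = lambda n, d: FeatureEntry(n, "buried_unsat", "count", d)
    return [
        f("bu_donor_N", "buried unsatisfied donor nitrogens"),
        f("bu_donor_O", "buried unsatisfied donor oxygens"),
        f("bu_acceptor_N", "buried unsatisfied acceptor nitrogens"),
        f("bu_acceptor_O", "buried unsatisfied acceptor oxygens"),
        f("bu_S", "buried unsatisfied sulfur atoms"),
        f("buried_polar_count", "ligand polar atoms with complexed SASA below threshold"),
        f("unsat_polar_count", "ligand polar atoms with no H-bond/salt-bridge partner"),
        f("buried_unsat_total", "buried and unsatisfied polar atoms, all classes"),
        FeatureEntry("buried_polar_fraction", "buried_unsat", "dimensionless",
                     "buried polar atoms / all polar atoms (0 if none)"),
        f("satisfied_buried_count", "buried polar atoms that do have a partner"),
    ]


def _pocket_shape_entries() -> list[FeatureEntry]:
    F = FeatureEntry
    return [
        F("pocket_volume", "pocket_shape", "A^3", "grid volume of enclosed, protein-free pocket space"),
        F("ligand_vdw_volume", "pocket_shape", "A^3", "grid volume of the ligand vdW envelope"),
        F("occupied_fraction", "pocket_shape", "dimensionless",
          "fraction of pocket space filled by the ligand"),
        F("enclosure", "pocket_shape", "dimensionless",
          "fraction of rays from the ligand centroid blocked by protein within 10 A"),
        F("pocket_depth", "pocket_shape", "A",
          "max depth of a ligand atom inside the pocket-residue convex hull"),
        F("n_pocket_residues", "pocket_shape", "count", "residues lining the pocket"),
        F("pocket_heavy_atom_count", "pocket_shape", "count", "heavy atoms lining the pocket"),
        F("pocket_polar_atom_fraction", "pocket_shape", "dimensionless",
          "N/O/S fraction of pocket heavy atoms"),
        F("pocket_apolar_carbon_fraction", "pocket_shape", "dimensionless",
          "apolar-carbon fraction of pocket heavy atoms"),
        F("pocket_charged_residue_fraction", "pocket_shape", "dimensionless",
          "fraction of pocket residues that are D/E/K/R"),
        F("pocket_aromatic_residue_fraction", "pocket_shape", "dimensionless",
          "fraction of pocket residues that are F/Y/W/H"),
        F("pocket_mean_dist_to_ligand_centroid", "pocket_shape", "A",
          "mean pocket-atom distance to the ligand centroid"),
        F("pocket_radius_of_gyration", "pocket_shape", "A", "Rg of pocket heavy atoms"),
        F("ligand_radius_of_gyration", "pocket_shape", "A", "Rg of ligand heavy atoms"),
        F("pocket_span", "pocket_shape", "A", "largest pocket-atom pairwise distance"),
        F("volume_per_ligand_heavy_atom", "pocket_shape", "A^3", "pocket volume / ligand heavy atoms"),
        F("depth_to_span_ratio", "pocket_shape", "dimensionless", "pocket depth / pocket span"),
        F("pocket_bbox_volume", "pocket_shape", "A^3",
          "canonical-frame bounding-box volume of pocket atoms"),
        F("pocket_compactness", "pocket_shape", "dimensionless",
          "pocket volume / bounding-box volume"),
        F("mean_ligand_buriedness", "pocket_shape", "dimensionless",
          "mean fraction of blocked axis rays per ligand atom"),
    ]


def _burial_misc_entries() -> list[FeatureEntry]:
    F = FeatureEntry
    a2 = "A^2"
    out = [
        F("ligand_sasa_complexed", "burial_misc", a2, "ligand SASA within the complex"),
        F("ligand_sasa_free", "burial_misc", a2, "ligand SASA alone"),
        F("ligand_buried_area", "burial_misc", a2, "free minus complexed ligand SASA"),
        F("ligand_buried_fraction", "burial_misc", "dimensionless",
          "buried area / free SASA"),
        F("interface_area_protein", "burial_misc", a2,
          "protein SASA lost upon ligand binding"),
        F("interface_area_total", "burial_misc", a2, "total buried surface, both sides"),
        F("ligand_polar_sasa_complexed", "burial_misc", a2, "complexed SASA of ligand N/O/S"),
        F("ligand_apolar_sasa_complexed", "burial_misc", a2, "complexed SASA of other ligand atoms"),
        F("ligand_polar_sasa_free", "burial_misc", a2, "free SASA of ligand N/O/S"),
        F("ligand_apolar_sasa_free", "burial_misc", a2, "free SASA of other ligand atoms"),
        F("ligand_polar_buried_fraction", "burial_misc", "dimensionless",
          "buried fraction of polar ligand surface"),
        F("ligand_apolar_buried_fraction", "burial_misc", "dimensionless",
          "buried fraction of apolar ligand surface"),
    ]
    for el in ["C", "N", "O", "S", "halogen"]:
        out.append(F(f"sasa_lig_{el}_complexed", "burial_misc", a2,
                     f"complexed SASA of ligand {el} atoms"))
    for el in ["C", "N", "O", "S", "halogen"]:
        out.append(F(f"buried_frac_lig_{el}", "burial_misc", "dimensionless",
                     f"buried fraction of ligand {el} surface (0 if absent)"))
    out += [
        F("frac_atoms_fully_buried", "burial_misc", "dimensionless",
          "ligand heavy atoms with complexed SASA < 0.1 A^2"),
        F("frac_atoms_half_buried", "burial_misc", "dimensionless",
          "ligand heavy atoms losing > 50% of free SASA"),
        F("mean_atom_burial", "burial_misc", "dimensionless",
          "mean per-atom buried fraction"),
        F("max_atom_sasa_complexed", "burial_misc", a2,
          "most exposed ligand heavy atom in the complex"),
        F("pocket_sasa_complexed", "burial_misc", a2, "pocket residue SASA in the complex"),
        F("pocket_sasa_apo", "burial_misc", a2, "pocket residue SASA without the ligand"),
        F("pocket_sasa_delta", "burial_misc", a2, "pocket SASA lost upon binding"),
        F("protein_total_sasa", "burial_misc", a2, "whole-protein SASA without the ligand"),
    ]
    return out


def default_registry() -> FeatureRegistry:
    """The default 166-descriptor registry (40/6/60/10/20/30 family quotas)."""
    return FeatureRegistry(
        _ligand2d_entries()
        + _ligand_energy_entries()
        + _interface_entries()
        + _buried_unsat_entries()
        + _pocket_shape_entries()
        + _burial_misc_entries()
    )


@dataclass
class FeatureVector:
    """One complex's values, aligned to a registry; missing values are NaN sentinels."""

    complex_id: str
    values: np.ndarray
    names: list[str]
    report: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ContractError("feature vector length must equal registry length")

    @property
    def n_sentinels(self) -> int:
        return int(np.isnan(self.values).sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


# ---------------------------------------------------------------------------
# ligand typing (shared with the decoy builder's color features)
# ---------------------------------------------------------------------------

def ligand_donor_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetSymbol() in ("N", "O", "S") and a.GetTotalNumHs(includeNeighbors=True) > 0]


def ligand_acceptor_atoms(mol: Chem.Mol) -> list[int]:
    out = []
    for a in mol.GetAtoms():
        if a.GetFormalCharge() > 0:
            continue
        if a.GetSymbol() == "O":
            out.append(a.GetIdx())
        elif a.GetSymbol() == "N" and a.GetTotalNumHs(includeNeighbors=True) == 0:
            # exclude trisubstituted aromatic N (pyrrole-type has H and is caught above)
            if a.GetIsAromatic() and a.GetDegree() == 3:
                continue
            out.append(a.GetIdx())
    return out


def ligand_cation_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetFormalCharge() > 0]


def ligand_anion_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetFormalCharge() < 0]


def ligand_apolar_carbons(mol: Chem.Mol) -> list[int]:
    out = []
    for a in mol.GetAtoms():
        if a.GetSymbol() != "C":
            continue
        if any(n.GetSymbol() in ("N", "O") for n in a.GetNeighbors()):
            continue
        out.append(a.GetIdx())
    return out


def ligand_halogen_atoms(mol: Chem.Mol) -> list[int]:
    """Cl/Br/I bound to carbon (fluorine is not a halogen-bond donor)."""
    return [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetSymbol() in ("Cl", "Br", "I")
        and any(n.GetSymbol() == "C" for n in a.GetNeighbors())
    ]


def ligand_aromatic_rings(mol: Chem.Mol) -> list[list[int]]:
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(list(ring))
    return rings


# ---------------------------------------------------------------------------
# protein typing
# ---------------------------------------------------------------------------

_PROT_ACCEPTOR = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"),
}
_PROT_POSITIVE = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
_PROT_NEGATIVE = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"), ("*", "OXT")}

_AROMATIC_RING_ATOMS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}


def _is_prot(table: set, res: str, atom: str) -> bool:
    return (res, atom) in table or ("*", atom) in table


@dataclass
class Contact:
    """One typed protein-ligand contact."""

    type: str
    protein_atom: int  # index into protein.atoms (ring contacts use the first ring atom)
    ligand_atom: int   # RDKit atom index (ligand ring contacts use the first ring atom)
    distance: float
    angle: float = float("nan")


@dataclass
class InteractionSet:
    """All typed contacts for one complex, deterministically ordered."""

    contacts: list[Contact]

    def by_type(self, t: str) -> list[Contact]:
        return [c for c in self.contacts if c.type == t]

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class InteractionCriteria:
    """Geometric contact criteria (all configurable)."""

    hbond_dist: float = 3.5
    hbond_angle: float = 120.0
    salt_bridge_dist: float = 4.0
    hydrophobic_dist: float = 4.5
    pi_stack_dist: float = 5.5
    pi_parallel_max: float = 30.0
    pi_tshape_min: float = 60.0
    cation_pi_dist: float = 6.0
    halogen_dist: float = 3.5
    halogen_angle: float = 140.0


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vh = np.linalg.svd(centered)
    return centroid, vh[2]


def detect_interactions(
    cplx: ProteinLigandComplex, criteria: InteractionCriteria | None = None
) -> InteractionSet:
    """Enumerate typed contacts between protein and ligand.

    Requires polar hydrogens (H-bond angles are measured through explicit
    donor hydrogens).  Contacts are ordered by (type, protein atom, ligand
    atom) so repeated runs produce identical lists.
    """
    crit = criteria or InteractionCriteria()
    prot = cplx.protein
    mol = cplx.ligand.mol
    lig_xyz = cplx.ligand.coords()
    lig_heavy_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    prot_heavy = [(i, a) for i, a in enumerate(prot.atoms) if a.element != "H"]

    if prot_heavy:
        pcoords = np.array([a.coords for _, a in prot_heavy])
        d_min = np.sqrt(
            ((pcoords[:, None, :] - lig_xyz[lig_heavy_idx][None, :, :]) ** 2).sum(axis=2)
        ).min()
        if d_min > 8.0:
            warnings.warn("no ligand heavy atom within 8 A of the protein", stacklevel=2)
            return InteractionSet([])

    contacts: list[Contact] = []

    # protein hydrogens attached to each heavy atom (distance-inferred bonds)
    h_atoms = [(i, a) for i, a in enumerate(prot.atoms) if a.element == "H"]
    attached_h: dict[int, list[int]] = {}
    for hi, h in h_atoms:
        for pi, p in prot_heavy:
            if p.residue_key == h.residue_key and np.linalg.norm(p.coords - h.coords) < 1.4:
                attached_h.setdefault(pi, []).append(hi)

    # distance-inferred polar carbons (carbon bonded to N/O)
    apolar_c: set[int] = set()
    if prot_heavy:
        tree = cKDTree(pcoords)
        for k, (pi, a) in enumerate(prot_heavy):
            if a.element != "C":
                continue
            near = tree.query_ball_point(a.coords, 1.65)
            if not any(prot_heavy[j][1].element in ("N", "O") for j in near if j != k):
                apolar_c.add(pi)

    prot_donors = [pi for pi in attached_h if prot.atoms[pi].element in ("N", "O", "S")]
    prot_acceptors = [
        pi for pi, a in prot_heavy if _is_prot(_PROT_ACCEPTOR, a.residue_name, a.name)
    ]
    prot_pos = [pi for pi, a in prot_heavy if _is_prot(_PROT_POSITIVE, a.residue_name, a.name)]
    prot_neg = [pi for pi, a in prot_heavy if _is_prot(_PROT_NEGATIVE, a.residue_name, a.name)]

    lig_donors = ligand_donor_atoms(mol)
    lig_acceptors = ligand_acceptor_atoms(mol)
    lig_cations = ligand_cation_atoms(mol)
    lig_anions = ligand_anion_atoms(mol)
    lig_apolar = ligand_apolar_carbons(mol)
    lig_halogens = ligand_halogen_atoms(mol)
    lig_rings = ligand_aromatic_rings(mol)

    lig_h_of: dict[int, list[int]] = {}
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 1:
            for n in a.GetNeighbors():
                lig_h_of.setdefault(n.GetIdx(), []).append(a.GetIdx())

    def p_xyz(i: int) -> np.ndarray:
        return prot.atoms[i].coords

    # --- hydrogen bonds ---
    for pi in prot_donors:  # protein donor -> ligand acceptor
        for la in lig_acceptors:
            d = float(np.linalg.norm(p_xyz(pi) - lig_xyz[la]))
            if d > crit.hbond_dist:
                continue
            for hi in attached_h[pi]:
                ang = _angle_deg(p_xyz(pi), p_xyz(hi), lig_xyz[la])
                if ang >= crit.hbond_angle:
                    contacts.append(Contact("hbond", pi, la, d, ang))
                    break
    for ld in lig_donors:  # ligand donor -> protein acceptor
        hs = lig_h_of.get(ld, [])
        for pa in prot_acceptors:
            d = float(np.linalg.norm(p_xyz(pa) - lig_xyz[ld]))
            if d > crit.hbond_dist:
                continue
            if hs:
                ok = False
                ang_best = 0.0
                for h in hs:
                    ang = _angle_deg(lig_xyz[ld], lig_xyz[h], p_xyz(pa))
                    if ang >= crit.hbond_angle:
                        ok, ang_best = True, ang
                        break
                if ok:
                    contacts.append(Contact("hbond", pa, ld, d, ang_best))
            else:
                # donor without explicit H (upstream protonation skipped): distance-only
                contacts.append(Contact("hbond", pa, ld, d))

    # --- salt bridges ---
    for pi in prot_pos:
        for la in lig_anions:
            d = float(np.linalg.norm(p_xyz(pi) - lig_xyz[la]))
            if d <= crit.salt_bridge_dist:
                contacts.append(Contact("salt_bridge", pi, la, d))
    for pi in prot_neg:
        for lc in lig_cations:
            d = float(np.linalg.norm(p_xyz(pi) - lig_xyz[lc]))
            if d <= crit.salt_bridge_dist:
                contacts.append(Contact("salt_bridge", pi, lc, d))

    # --- hydrophobic ---
    for pi in sorted(apolar_c):
        for lc in lig_apolar:
            d = float(np.linalg.norm(p_xyz(pi) - lig_xyz[lc]))
            if d <= crit.hydrophobic_dist:
                contacts.append(Contact("hydrophobic", pi, lc, d))

    # --- aromatic rings of the protein ---
    prot_rings: list[tuple[int, np.ndarray, np.ndarray]] = []
    atom_index = {}
    for i, a in enumerate(prot.atoms):
        atom_index[(a.residue_key, a.name)] = i
    for res in prot.residues(polymer_only=True):
        for ring_names in _AROMATIC_RING_ATOMS.get(res.name, []):
            idxs = [atom_index.get((res.key, n)) for n in ring_names]
            if any(i is None for i in idxs):
                continue
            coords = np.array([p_xyz(i) for i in idxs])
            centroid, normal = _ring_geometry(coords)
            prot_rings.append((idxs[0], centroid, normal))

    lig_ring_geo = []
    for ring in lig_rings:
        centroid, normal = _ring_geometry(lig_xyz[ring])
        lig_ring_geo.append((ring[0], centroid, normal))

    # --- pi stacking ---
    for pfirst, pcen, pnorm in prot_rings:
        for lfirst, lcen, lnorm in lig_ring_geo:
            d = float(np.linalg.norm(pcen - lcen))
            if d > crit.pi_stack_dist:
                continue
            ang = float(np.degrees(np.arccos(np.clip(abs(np.dot(pnorm, lnorm)), 0, 1))))
            if ang <= crit.pi_parallel_max or ang >= crit.pi_tshape_min:
                contacts.append(Contact("pi_stack", pfirst, lfirst, d, ang))

    # --- cation-pi ---
    for pi in prot_pos:
        for lfirst, lcen, _ in lig_ring_geo:
            d = float(np.linalg.norm(p_xyz(pi) - lcen))
            if d <= crit.cation_pi_dist:
                contacts.append(Contact("cation_pi", pi, lfirst, d))
    for pfirst, pcen, _ in prot_rings:
        for lc in lig_cations:
            d = float(np.linalg.norm(pcen - lig_xyz[lc]))
            if d <= crit.cation_pi_dist:
                contacts.append(Contact("cation_pi", pfirst, lc, d))

    # --- halogen bonds ---
    for lx in lig_halogens:
        carbon = next(
            n.GetIdx() for n in mol.GetAtomWithIdx(lx).GetNeighbors() if n.GetSymbol() == "C"
        )
        for pa in prot_acceptors:
            d = float(np.linalg.norm(p_xyz(pa) - lig_xyz[lx]))
            if d > crit.halogen_dist:
                continue
            ang = _angle_deg(lig_xyz[carbon], lig_xyz[lx], p_xyz(pa))
            if ang >= crit.halogen_angle:
                contacts.append(Contact("halogen_bond", pa, lx, d, ang))

    contacts.sort(key=lambda c: (c.type, c.protein_atom, c.ligand_atom))
    return InteractionSet(contacts)


# ---------------------------------------------------------------------------
# buried unsatisfied polar atoms
# ---------------------------------------------------------------------------

BURIAL_SASA_THRESHOLD = 0.1  # A^2; below this a polar atom counts as buried


def count_buried_unsat(
    cplx: ProteinLigandComplex,
    interactions: InteractionSet | None = None,
    threshold: float = BURIAL_SASA_THRESHOLD,
    n_points: int = DEFAULT_SASA_POINTS,
) -> dict[str, int | float]:
    """Buried-unsatisfied counts for ligand polar atoms, per polar-group class.

    A ligand polar atom (N/O/S) is *buried* when its SASA within the complex
    falls below ``threshold``; it is *unsatisfied* when it takes part in no
    hydrogen-bond or salt-bridge contact.
    """
    if interactions is None:
        interactions = detect_interactions(cplx)
    mol = cplx.ligand.mol
    lig_xyz = cplx.ligand.coords()
    lig_heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]

    prot_heavy = [a for a in cplx.protein.atoms if a.element != "H"]
    coords = np.vstack([np.array([a.coords for a in prot_heavy]), lig_xyz[lig_heavy]])
    radii = np.array(
        [vdw_radius(a.element) for a in prot_heavy]
        + [vdw_radius(mol.GetAtomWithIdx(i).GetSymbol()) for i in lig_heavy]
    )
    # quadrature in the ligand's canonical frame: burial is then exactly
    # invariant under joint rigid motion of the complex
    centroid, axes = canonical_frame(lig_xyz[lig_heavy])
    sasa = compute_sasa((coords - centroid) @ axes, radii, n_points=n_points)
    lig_sasa = {idx: sasa.areas[len(prot_heavy) + k] for k, idx in enumerate(lig_heavy)}

    satisfied = {
        c.ligand_atom for c in interactions.contacts if c.type in ("hbond", "salt_bridge")
    }

    counts = {k: 0 for k in ("bu_donor_N", "bu_donor_O", "bu_acceptor_N", "bu_acceptor_O", "bu_S")}
    buried_polar = unsat_polar = buried_unsat = satisfied_buried = n_polar = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O", "S") or atom.GetAtomicNum() == 1:
            continue
        idx = atom.GetIdx()
        n_polar += 1
        buried = lig_sasa.get(idx, 0.0) < threshold
        unsat = idx not in satisfied
        if buried:
            buried_polar += 1
            if not unsat:
                satisfied_buried += 1
        if unsat:
            unsat_polar += 1
        if buried and unsat:
            buried_unsat += 1
            if sym == "S":
                counts["bu_S"] += 1
            elif atom.GetTotalNumHs(includeNeighbors=True) > 0:
                counts[f"bu_donor_{sym}"] += 1
            else:
                counts[f"bu_acceptor_{sym}"] += 1
    counts.update(
        buried_polar_count=buried_polar,
        unsat_polar_count=unsat_polar,
        buried_unsat_total=buried_unsat,
        buried_polar_fraction=(buried_polar / n_polar) if n_polar else 0.0,
        satisfied_buried_count=satisfied_buried,
    )
    return counts


# ---------------------------------------------------------------------------
# ligand 2D descriptors
# ---------------------------------------------------------------------------

def ligand_descriptors_2d(lig) -> dict[str, float]:
    """The ligand2d feature block (graph-only; pose independent)."""
    mol = Chem.RemoveHs(Chem.Mol(lig.mol))
    try:
        Chem.SanitizeMol(mol)
        ri = mol.GetRingInfo()
        ring_sizes = [len(r) for r in ri.AtomRings()]
        stereo = Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
        unassigned = sum(1 for _, tag in stereo if tag == "?")
        counts = {s: 0 for s in ("C", "N", "O", "S", "P")}
        halogens = 0
        for a in mol.GetAtoms():
            s = a.GetSymbol()
            if s in counts:
                counts[s] += 1
            elif s in ("F", "Cl", "Br", "I"):
                halogens += 1
        return {
            "mol_weight": Descriptors.MolWt(mol),
            "heavy_atom_count": mol.GetNumHeavyAtoms(),
            "ring_count": rdMolDescriptors.CalcNumRings(mol),
            "aromatic_ring_count": rdMolDescriptors.CalcNumAromaticRings(mol),
            "aliphatic_ring_count": rdMolDescriptors.CalcNumAliphaticRings(mol),
            "saturated_ring_count": rdMolDescriptors.CalcNumSaturatedRings(mol),
            "heterocycle_count": rdMolDescriptors.CalcNumHeterocycles(mol),
            "aromatic_heterocycle_count": rdMolDescriptors.CalcNumAromaticHeterocycles(mol),
            "largest_ring_size": max(ring_sizes) if ring_sizes else 0,
            "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
            "hbond_donors": rdMolDescriptors.CalcNumHBD(mol),
            "hbond_acceptors": rdMolDescriptors.CalcNumHBA(mol),
            "tpsa": rdMolDescriptors.CalcTPSA(mol),
            "clogp": Crippen.MolLogP(mol),
            "molar_refractivity": Crippen.MolMR(mol),
            "formal_charge": Chem.GetFormalCharge(mol),
            "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
            "stereocenters": len(stereo),
            "unspecified_stereocenters": unassigned,
            "amide_bond_count": rdMolDescriptors.CalcNumAmideBonds(mol),
            "spiro_atom_count": rdMolDescriptors.CalcNumSpiroAtoms(mol),
            "bridgehead_atom_count": rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
            "carbon_count": counts["C"],
            "nitrogen_count": counts["N"],
            "oxygen_count": counts["O"],
            "sulfur_count": counts["S"],
            "halogen_count": halogens,
            "phosphorus_count": counts["P"],
            "balaban_j": GraphDescriptors.BalabanJ(mol),
            "bertz_ct": GraphDescriptors.BertzCT(mol),
            "chi0v": GraphDescriptors.Chi0v(mol),
            "chi1v": GraphDescriptors.Chi1v(mol),
            "chi2v": GraphDescriptors.Chi2v(mol),
            "chi3v": GraphDescriptors.Chi3v(mol),
            "kappa1": GraphDescriptors.Kappa1(mol),
            "kappa2": GraphDescriptors.Kappa2(mol),
            "kappa3": GraphDescriptors.Kappa3(mol),
            "hall_kier_alpha": GraphDescriptors.HallKierAlpha(mol),
            "labute_asa": rdMolDescriptors.CalcLabuteASA(mol),
            "qed": QED.qed(mol),
        }
    except Exception as exc:
        raise ContentError(f"descriptor_error: {exc}") from exc


# ---------------------------------------------------------------------------
# ligand strain
# ---------------------------------------------------------------------------

def _mmff_energy(mol: Chem.Mol, conf_id: int = -1) -> float:
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is None:
        raise ContentError("MMFF94 setup failed (exotic atom type)")
    ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf_id)
    if ff is None:
        raise ContentError("MMFF94 force field construction failed")
    return float(ff.CalcEnergy())


def ligand_strain(
    lig, n_conformers: int = 30, seed: int = 20240901
) -> dict[str, float]:
    """MMFF94 pose energy and conformational strain.

    Strain is the bound-pose energy minus the minimum energy over a relaxed
    ETKDG conformer ensemble (the relaxed pose itself is included in the
    ensemble, so strain >= 0 up to minimizer tolerance).
    """
    if not lig.has_pose:
        raise ContentError("ligand has no 3D pose")
    mol = Chem.AddHs(Chem.Mol(lig.mol), addCoords=True)
    Chem.SanitizeMol(mol)
    pose_e = _mmff_energy(mol)

    # the ensemble is embedded from the graph alone (pose-independent, so
    # strain is exactly invariant under rigid motion of the pose)
    probe = Chem.AddHs(Chem.RemoveHs(Chem.Mol(mol)))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMultipleConfs(probe, numConfs=n_conformers, params=params)
    if probe.GetNumConformers() == 0:
        raise ContentError("conformer embedding failed")
    results = AllChem.MMFFOptimizeMoleculeConfs(probe, maxIters=500)
    energies = [e for ok, e in results if ok == 0]
    if not energies:
        raise ContentError("conformer minimization failed for every conformer")
    e_min = min(energies)
    e_max = max(energies)
    strain = pose_e - e_min  # may dip slightly below 0 within minimizer tolerance
    mol_noh = Chem.RemoveHs(mol)
    rotors = rdMolDescriptors.CalcNumRotatableBonds(mol_noh)
    return {
        "pose_energy": pose_e,
        "ensemble_min_energy": e_min,
        "strain_energy": strain,
        "strain_per_heavy_atom": strain / max(1, mol_noh.GetNumHeavyAtoms()),
        "strain_per_rotor": strain / (1.0 + rotors),
        "ensemble_energy_range": e_max - e_min,
    }


# ---------------------------------------------------------------------------
# pocket shape
# ---------------------------------------------------------------------------

def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and a rotation whose columns are principal axes of ``coords``.

    Axis signs are fixed by the third central moment along each axis (the
    axis points toward positive skewness), making the frame equivariant
    under rigid transforms for generic point sets.
    """
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / max(1, len(coords))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    for k in range(3):
        skew = float(((centered @ axes[:, k]) ** 3).sum())
        if skew < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return centroid, axes


def _ray_hits(
    origins: np.ndarray, directions: np.ndarray, centers: np.ndarray,
    radii: np.ndarray, max_dist: float,
) -> np.ndarray:
    """Boolean (n_origins, n_dirs): does the ray hit any sphere within max_dist?"""
    n_o, n_d = len(origins), len(directions)
    hits = np.zeros((n_o, n_d), dtype=bool)
    for j, d in enumerate(directions):
        rel = centers[None, :, :] - origins[:, None, :]   # (o, a, 3)
        t = rel @ d                                        # projection along ray
        perp2 = (rel ** 2).sum(axis=2) - t ** 2
        hit = (t > 0) & (t < max_dist) & (perp2 <= (radii ** 2)[None, :])
        hits[:, j] = hit.any(axis=1)
    return hits


def pocket_shape(
    cplx: ProteinLigandComplex,
    grid_spacing: float = 0.6,
    pocket_radius: float = 6.0,
    n_rays: int = 240,
    ray_length: float = 10.0,
) -> dict[str, float]:
    """Grid- and ray-based pocket geometry features.

    Rays are cast along a Fibonacci direction set expressed in the ligand's
    canonical principal-axes frame, so every quantity is invariant under a
    joint rigid transform of the complex.
    """
    if grid_spacing <= 0:
        raise ContractError("grid spacing must be positive")
    pocket = extract_pocket(cplx, pocket_radius)
    lig_xyz = cplx.ligand.coords(heavy_only=True)
    lig_elements = [
        a.GetSymbol() for a in cplx.ligand.mol.GetAtoms() if a.GetAtomicNum() > 1
    ]
    lig_radii = np.array([vdw_radius(e) for e in lig_elements])
    prot_atoms = [a for a in cplx.protein.atoms if a.element != "H"]
    prot_xyz = np.array([a.coords for a in prot_atoms])
    prot_radii = np.array([vdw_radius(a.element) for a in prot_atoms])

    centroid, axes = canonical_frame(lig_xyz)
    dirs = fibonacci_sphere(n_rays) @ axes.T
    # rays see probe-expanded atoms (a probe-sized gap does not count as open)
    ray_radii = prot_radii + DEFAULT_PROBE

    # enclosure: rays from the ligand centroid
    enclosure = float(
        _ray_hits(centroid[None, :], dirs, prot_xyz, ray_radii, ray_length).mean()
    )

    # per-atom buriedness along the 6 canonical axis directions
    axis_dirs = np.vstack([axes.T, -axes.T])
    burial = _ray_hits(lig_xyz, axis_dirs, prot_xyz, ray_radii, ray_length)
    mean_buriedness = float(burial.mean())

    # grid volumes, in the canonical frame so counts are transform-invariant
    local_lig = (lig_xyz - centroid) @ axes
    local_prot = (prot_xyz - centroid) @ axes
    lo = local_lig.min(axis=0) - 4.0
    hi = local_lig.max(axis=0) + 4.0
    grids = [np.arange(lo[k], hi[k] + grid_spacing, grid_spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    pts_local = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    prot_tree = cKDTree(local_prot)
    rmax_p = float(prot_radii.max())
    inside_protein = np.zeros(len(pts_local), dtype=bool)
    cand = prot_tree.query_ball_point(pts_local, rmax_p)
    for i, idxs in enumerate(cand):
        if idxs:
            d = np.linalg.norm(local_prot[idxs] - pts_local[i], axis=1)
            inside_protein[i] = bool((d <= prot_radii[idxs]).any())

    lig_tree = cKDTree(local_lig)
    rmax_l = float(lig_radii.max())
    inside_ligand = np.zeros(len(pts_local), dtype=bool)
    cand = lig_tree.query_ball_point(pts_local, rmax_l)
    for i, idxs in enumerate(cand):
        if idxs:
            d = np.linalg.norm(local_lig[idxs] - pts_local[i], axis=1)
            inside_ligand[i] = bool((d <= lig_radii[idxs]).any())

    # a free grid point belongs to the pocket when >= 4 of the 6 axis rays
    # (cast in the canonical frame) hit protein within the ray length
    free = ~inside_protein
    free_pts = pts_local[free]
    axis_local = np.vstack([np.eye(3), -np.eye(3)])
    buried_rays = _ray_hits(free_pts, axis_local, local_prot, prot_radii + DEFAULT_PROBE,
                            ray_length)
    enclosed = buried_rays.sum(axis=1) >= 4
    voxel = grid_spacing ** 3
    pocket_mask = np.zeros(len(pts_local), dtype=bool)
    pocket_mask[np.where(free)[0][enclosed]] = True
    pocket_volume = float(pocket_mask.sum() * voxel)
    ligand_volume = float(inside_ligand.sum() * voxel)
    occupied = float((pocket_mask & inside_ligand).sum() * voxel)
    occupied_fraction = occupied / pocket_volume if pocket_volume > 0 else 0.0

    # convex-hull depth
    pocket_heavy = np.vstack([r.heavy_coords() for r in pocket])
    depth = 0.0
    try:
        hull = ConvexHull(pocket_heavy)
        eq = hull.equations  # A x + b <= 0 inside
        margins = -(lig_xyz @ eq[:, :3].T + eq[:, 3][None, :])
        inside = (margins >= 0).all(axis=1)
        if inside.any():
            depth = float(margins[inside].min(axis=1).max())
    except QhullError:
        depth = 0.0

    polar = sum(1 for r in pocket for a in r.atoms if a.element in ("N", "O", "S"))
    n_heavy = int(pocket_heavy.shape[0])
    apolar_c = 0
    ptree = cKDTree(pocket_heavy)
    flat = [a for r in pocket for a in r.atoms if a.element != "H"]
    for i, a in enumerate(flat):
        if a.element != "C":
            continue
        near = ptree.query_ball_point(a.coords, 1.65)
        if not any(flat[j].element in ("N", "O") for j in near if j != i):
            apolar_c += 1
    charged = sum(1 for r in pocket if r.name in ("ASP", "GLU", "LYS", "ARG"))
    aromatic = sum(1 for r in pocket if r.name in ("PHE", "TYR", "TRP", "HIS"))

    dists = np.linalg.norm(pocket_heavy - centroid, axis=1)
    pk_centroid = pocket_heavy.mean(axis=0)
    rg_pocket = float(np.sqrt(((pocket_heavy - pk_centroid) ** 2).sum(axis=1).mean()))
    lg_centroid = lig_xyz.mean(axis=0)
    rg_lig = float(np.sqrt(((lig_xyz - lg_centroid) ** 2).sum(axis=1).mean()))
    span = float(np.sqrt(((pocket_heavy[:, None, :] - pocket_heavy[None, :, :]) ** 2)
                         .sum(axis=2).max()))
    local_pocket = (pocket_heavy - centroid) @ axes
    bbox = np.prod(local_pocket.max(axis=0) - local_pocket.min(axis=0))

    return {
        "pocket_volume": pocket_volume,
        "ligand_vdw_volume": ligand_volume,
        "occupied_fraction": occupied_fraction,
        "enclosure": enclosure,
        "pocket_depth": depth,
        "n_pocket_residues": float(len(pocket)),
        "pocket_heavy_atom_count": float(n_heavy),
        "pocket_polar_atom_fraction": polar / n_heavy if n_heavy else 0.0,
        "pocket_apolar_carbon_fraction": apolar_c / n_heavy if n_heavy else 0.0,
        "pocket_charged_residue_fraction": charged / len(pocket),
        "pocket_aromatic_residue_fraction": aromatic / len(pocket),
        "pocket_mean_dist_to_ligand_centroid": float(dists.mean()),
        "pocket_radius_of_gyration": rg_pocket,
        "ligand_radius_of_gyration": rg_lig,
        "pocket_span": span,
        "volume_per_ligand_heavy_atom": pocket_volume / max(1, lig_xyz.shape[0]),
        "depth_to_span_ratio": depth / span if span > 0 else 0.0,
        "pocket_bbox_volume": float(bbox),
        "pocket_compactness": pocket_volume / bbox if bbox > 0 else 0.0,
        "mean_ligand_buriedness": mean_buriedness,
    }


# ---------------------------------------------------------------------------
# SASA partition features
# ---------------------------------------------------------------------------

def _element_class(sym: str) -> str:
    if sym in ("N", "O", "S"):
        return sym
    if sym in ("F", "Cl", "Br", "I"):
        return "halogen"
    return "C"


def burial_features(
    cplx: ProteinLigandComplex,
    pocket_radius: float = 6.0,
    n_points: int = DEFAULT_SASA_POINTS,
) -> dict[str, float]:
    """SASA partitions: ligand/protein/pocket areas free vs complexed."""
    mol = cplx.ligand.mol
    lig_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    lig_sym = [mol.GetAtomWithIdx(i).GetSymbol() for i in lig_idx]
    lig_xyz = cplx.ligand.coords()[lig_idx]
    lig_radii = np.array([vdw_radius(s) for s in lig_sym])

    prot_atoms = [a for a in cplx.protein.atoms if a.element != "H"]
    prot_xyz = np.array([a.coords for a in prot_atoms])
    prot_radii = np.array([vdw_radius(a.element) for a in prot_atoms])

    # canonical ligand frame keeps the quadrature rigid-invariant
    centroid, axes = canonical_frame(lig_xyz)
    lig_xyz = (lig_xyz - centroid) @ axes
    prot_xyz = (prot_xyz - centroid) @ axes

    free = compute_sasa(lig_xyz, lig_radii, n_points=n_points).areas
    apo = compute_sasa(prot_xyz, prot_radii, n_points=n_points).areas
    both = compute_sasa(
        np.vstack([prot_xyz, lig_xyz]), np.concatenate([prot_radii, lig_radii]),
        n_points=n_points,
    ).areas
    prot_cplx = both[: len(prot_atoms)]
    lig_cplx = both[len(prot_atoms):]

    polar_mask = np.array([s in ("N", "O", "S") for s in lig_sym])
    lig_free_tot = float(free.sum())
    lig_cplx_tot = float(lig_cplx.sum())
    buried_area = lig_free_tot - lig_cplx_tot
    polar_free = float(free[polar_mask].sum())
    polar_cplx = float(lig_cplx[polar_mask].sum())
    apolar_free = float(free[~polar_mask].sum())
    apolar_cplx = float(lig_cplx[~polar_mask].sum())

    out = {
        "ligand_sasa_complexed": lig_cplx_tot,
        "ligand_sasa_free": lig_free_tot,
        "ligand_buried_area": buried_area,
        "ligand_buried_fraction": buried_area / lig_free_tot if lig_free_tot > 0 else 0.0,
        "interface_area_protein": float(apo.sum() - prot_cplx.sum()),
        "interface_area_total": float(apo.sum() + lig_free_tot - both.sum()),
        "ligand_polar_sasa_complexed": polar_cplx,
        "ligand_apolar_sasa_complexed": apolar_cplx,
        "ligand_polar_sasa_free": polar_free,
        "ligand_apolar_sasa_free": apolar_free,
        "ligand_polar_buried_fraction":
            (polar_free - polar_cplx) / polar_free if polar_free > 0 else 0.0,
        "ligand_apolar_buried_fraction":
            (apolar_free - apolar_cplx) / apolar_free if apolar_free > 0 else 0.0,
    }
    for el in ["C", "N", "O", "S", "halogen"]:
        mask = np.array([_element_class(s) == el for s in lig_sym])
        el_cplx = float(lig_cplx[mask].sum()) if mask.any() else 0.0
        el_free = float(free[mask].sum()) if mask.any() else 0.0
        out[f"sasa_lig_{el}_complexed"] = el_cplx
        out[f"buried_frac_lig_{el}"] = (el_free - el_cplx) / el_free if el_free > 0 else 0.0

    atom_burial = np.where(free > 0, (free - lig_cplx) / np.maximum(free, 1e-12), 0.0)
    out.update(
        frac_atoms_fully_buried=float((lig_cplx < BURIAL_SASA_THRESHOLD).mean()),
        frac_atoms_half_buried=float((atom_burial > 0.5).mean()),
        mean_atom_burial=float(atom_burial.mean()),
        max_atom_sasa_complexed=float(lig_cplx.max()),
    )

    pocket = extract_pocket(cplx, pocket_radius)
    pocket_keys = {r.key for r in pocket}
    pocket_mask = np.array([a.residue_key in pocket_keys for a in prot_atoms])
    pk_cplx = float(prot_cplx[pocket_mask].sum())
    pk_apo = float(apo[pocket_mask].sum())
    out.update(
        pocket_sasa_complexed=pk_cplx,
        pocket_sasa_apo=pk_apo,
        pocket_sasa_delta=pk_apo - pk_cplx,
        protein_total_sasa=float(apo.sum()),
    )
    return out


# ---------------------------------------------------------------------------
# interface feature block
# ---------------------------------------------------------------------------

def interface_features(
    cplx: ProteinLigandComplex, interactions: InteractionSet | None = None
) -> dict[str, float]:
    """The interface block: typed-contact statistics and raw contact geometry."""
    inter = interactions if interactions is not None else detect_interactions(cplx)
    prot = cplx.protein
    mol = cplx.ligand.mol
    out: dict[str, float] = {}
    for t in CONTACT_TYPES:
        cs = inter.by_type(t)
        ds = [c.distance for c in cs]
        out[f"{t}_count"] = float(len(cs))
        out[f"{t}_min_distance"] = float(min(ds)) if ds else 0.0
        out[f"{t}_mean_distance"] = float(np.mean(ds)) if ds else 0.0

    hb = inter.by_type("hbond")
    lig_donor_idx = set(ligand_donor_atoms(mol))
    out["hbond_ligand_donor_count"] = float(sum(1 for c in hb if c.ligand_atom in lig_donor_idx))
    out["hbond_protein_donor_count"] = float(len(hb)) - out["hbond_ligand_donor_count"]

    for res in RESIDUE_TYPES:
        out[f"contacts_res_{res}"] = 0.0
    for c in inter.contacts:
        rname = prot.atoms[c.protein_atom].residue_name
        if f"contacts_res_{rname}" in out:
            out[f"contacts_res_{rname}"] += 1.0

    for el in ["C", "N", "O", "S", "halogen"]:
        out[f"contacts_lig_{el}"] = 0.0
    for c in inter.contacts:
        sym = mol.GetAtomWithIdx(c.ligand_atom).GetSymbol()
        out[f"contacts_lig_{_element_class(sym)}"] += 1.0

    lig_xyz = cplx.ligand.coords(heavy_only=True)
    prot_xyz = prot.heavy_coords()
    d = np.sqrt(((prot_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2))
    for lo in np.arange(2.5, 7.0, 0.5):
        out[f"heavy_pairs_{lo:.1f}_{lo + 0.5:.1f}"] = float(((d >= lo) & (d < lo + 0.5)).sum())

    n = len(inter)
    angles = [c.angle for c in hb if np.isfinite(c.angle)]
    out.update(
        total_contact_count=float(n),
        contact_density=n / max(1, lig_xyz.shape[0]),
        n_contact_residues=float(len({prot.atoms[c.protein_atom].residue_key
                                      for c in inter.contacts})),
        hbond_mean_angle=float(np.mean(angles)) if angles else 0.0,
        min_heavy_atom_distance=float(d.min()) if d.size else 0.0,
        polar_contact_fraction=(
            (out["hbond_count"] + out["salt_bridge_count"]) / n if n else 0.0
        ),
    )
    return out


# ---------------------------------------------------------------------------
# featurize
# ---------------------------------------------------------------------------

@dataclass
class FeaturizeSettings:
    """Numerical knobs for the feature engine (defaults documented in docs)."""

    pocket_radius: float = 6.0
    grid_spacing: float = 0.6
    n_rays: int = 240
    sasa_points: int = DEFAULT_SASA_POINTS
    strain_conformers: int = 30
    strain_seed: int = 20240901


def featurize(
    cplx: ProteinLigandComplex,
    registry: FeatureRegistry | None = None,
    settings: FeaturizeSettings | None = None,
) -> FeatureVector:
    """One value per registry entry for one complex.

    Families fail independently: an error in one family writes NaN
    sentinels for that family only and records the reason in the vector's
    report.  Polar hydrogens are assigned on the fly when absent.
    """
    registry = registry or default_registry()
    settings = settings or FeaturizeSettings()
    if "protonation" not in cplx.meta:
        cplx = assign_polar_hydrogens(cplx)

    values: dict[str, float] = {}
    report: dict[str, str] = {}

    def run_family(family: str, fn) -> None:
        names = registry.family_names(family)
        try:
            block = fn()
            missing = [n for n in names if n not in block]
            if missing:
                raise ContractError(f"family {family} missing {missing[:3]}")
            for n in names:
                values[n] = float(block[n])
        except Exception as exc:
            for n in names:
                values[n] = SENTINEL
            report[family] = str(exc)

    interactions: list[InteractionSet] = []

    def get_interactions() -> InteractionSet:
        if not interactions:
            interactions.append(detect_interactions(cplx))
        return interactions[0]

    run_family("ligand2d", lambda: ligand_descriptors_2d(cplx.ligand))
    run_family(
        "ligand_energy",
        lambda: ligand_strain(cplx.ligand, settings.strain_conformers, settings.strain_seed),
    )
    run_family("interface", lambda: interface_features(cplx, get_interactions()))
    run_family(
        "buried_unsat",
        lambda: count_buried_unsat(cplx, get_interactions(), n_points=settings.sasa_points),
    )
    run_family(
        "pocket_shape",
        lambda: pocket_shape(cplx, settings.grid_spacing, settings.pocket_radius,
                             settings.n_rays),
    )
    run_family(
        "burial_misc",
        lambda: burial_features(cplx, settings.pocket_radius, settings.sasa_points),
    )

    vec = np.array([values[n] for n in registry.names])
    return FeatureVector(cplx.complex_id, vec, registry.names, report)
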
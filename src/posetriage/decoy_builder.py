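"""Property-matched decoy construction.

From an active ligand and a local candidate pool: filter candidates to the
active's physicochemical neighbourhood, generate low-energy conformers,
align each conformer onto the active pose by maximizing Gaussian volume
overlap, score the alignment with shape + pharmacophore ("color") Tanimoto
coefficients, keep the top three candidates by the combined score, and place
them into the cognate pocket with the alignment transform.

The molecular density is a sum of atom-centred Gaussians whose amplitude is
2.7 and whose width is chosen so an isolated atom's Gaussian volume equals
its van der Waals sphere volume; overlap integrals are closed-form pairwise
Gaussian products.  Shape Tanimoto is O_AB / (O_AA + O_BB - O_AB); color
Tanimoto applies the same formula to pharmacophore-typed pseudo-atoms
(donor, acceptor, anion, cation, aromatic-ring centroid, hydrophobe), with
overlap accumulated only between features of the same type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors, rdMolAlign
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .complex_io import LigandMolecule, ProteinLigandComplex, ProteinStructure
from .curation import DruglikeRules, filter_ligand_druglike
from .errors import ContentError, ContractError, StructureError
from .feature_engine import (
    ligand_acceptor_atoms,
    ligand_anion_atoms,
    ligand_apolar_carbons,
    ligand_aromatic_rings,
    ligand_cation_atoms,
    ligand_donor_atoms,
)
from .geometry import rigid_transform, validate_rotation, vdw_radius

GAUSSIAN_AMPLITUDE = 2.7
COLOR_RADIUS = 1.0  # Angstrom, all pharmacophore pseudo-atoms
CLASH_DISTANCE = 1.5  # Angstrom, protein-ligand heavy atom


# ---------------------------------------------------------------------------
# property matching
# ---------------------------------------------------------------------------

@dataclass
class MatchWindows:
    """Per-descriptor tolerances defining 'physicochemically matched'."""

    mw: float = 25.0
    logp: float = 1.0
    rotors: int = 2
    hbd: int = 1
    hba: int = 1
    charge_equal: bool = True
    max_candidates: int = 50


def _properties(mol: Chem.Mol) -> dict[str, float]:
    m = Chem.RemoveHs(mol)
    return {
        "mw": Descriptors.MolWt(m),
        "logp": Crippen.MolLogP(m),
        "rotors": rdMolDescriptors.CalcNumRotatableBonds(m),
        "hbd": rdMolDescriptors.CalcNumHBD(m),
        "hba": rdMolDescriptors.CalcNumHBA(m),
        "charge": Chem.GetFormalCharge(m),
    }


@dataclass
class CandidateDecoy:
    """A pool molecule accepted as physicochemically matched to an active."""

    molecule: LigandMolecule
    property_deltas: dict[str, float]
    conformers: list[np.ndarray] = field(default_factory=list)


def match_properties(
    active: LigandMolecule,
    pool: list[LigandMolecule],
    windows: MatchWindows | None = None,
    rules: DruglikeRules | None = None,
) -> list[CandidateDecoy]:
    """Candidates whose descriptor deltas sit inside every window.

    The active itself (identical graph) is excluded; accepted candidates
    must also pass the same drug-likeness filters applied to actives.  At
    most ``max_candidates`` are returned, closest aggregate delta first.
    """
    if not pool:
        raise ContractError("candidate pool is empty")
    win = windows or MatchWindows()
    ref = _properties(active.mol)
    ref_smiles = active.canonical_smiles()
    scored: list[tuple[float, str, CandidateDecoy]] = []
    for cand in pool:
        if cand.canonical_smiles() == ref_smiles:
            continue
        props = _properties(cand.mol)
        deltas = {k: props[k] - ref[k] for k in props}
        if abs(deltas["mw"]) > win.mw or abs(deltas["logp"]) > win.logp:
            continue
        if abs(deltas["rotors"]) > win.rotors:
            continue
        if abs(deltas["hbd"]) > win.hbd or abs(deltas["hba"]) > win.hba:
            continue
        if win.charge_equal and deltas["charge"] != 0:
            continue
        if not filter_ligand_druglike(cand, rules).passed:
            continue
        aggregate = (
            abs(deltas["mw"]) / win.mw
            + abs(deltas["logp"]) / win.logp
            + abs(deltas["rotors"]) / max(1, win.rotors)
            + abs(deltas["hbd"]) / max(1, win.hbd)
            + abs(deltas["hba"]) / max(1, win.hba)
        )
        scored.append((aggregate, cand.name, CandidateDecoy(cand, deltas)))
    if not scored:
        warnings.warn("no pool molecule matched the property windows", stacklevel=2)
        return []
    scored.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in scored[: win.max_candidates]]


# ---------------------------------------------------------------------------
# conformers
# ---------------------------------------------------------------------------

def gen_conformers(
    mol: LigandMolecule, n: int = 500, seed: int = 0, rmsd_threshold: float = 0.5
) -> list[np.ndarray]:
    """Up to ``n`` ETKDG conformers, MMFF-relaxed, deduplicated by heavy-atom RMSD.

    Deterministic for a fixed seed.  Returns full-atom coordinate arrays in
    energy order (lowest first).
    """
    if n < 1:
        raise ContractError("conformer count must be >= 1")
    work = Chem.AddHs(Chem.Mol(mol.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    cids = AllChem.EmbedMultipleConfs(work, numConfs=n, params=params)
    if len(cids) == 0:
        raise StructureError(f"conformer embedding failed for {mol.name}")
    results = AllChem.MMFFOptimizeMoleculeConfs(work, maxIters=500)
    energies = [(e if ok == 0 else np.inf) for ok, e in results]
    order = sorted(range(len(cids)), key=lambda i: (energies[i], i))

    heavy = [a.GetIdx() for a in work.GetAtoms() if a.GetAtomicNum() > 1]
    kept: list[int] = []
    for i in order:
        if not np.isfinite(energies[i]):
            continue
        duplicate = False
        for j in kept:
            rms = rdMolAlign.AlignMol(
                Chem.Mol(work), Chem.Mol(work), prbCid=cids[i], refCid=cids[j],
                atomMap=[(k, k) for k in heavy],
            )
            if rms < rmsd_threshold:
                duplicate = True
                break
        if not duplicate:
            kept.append(i)
    no_h = Chem.RemoveHs(work)
    keep_idx = [a.GetIdx() for a in work.GetAtoms() if a.GetAtomicNum() > 1]
    out = []
    for i in kept:
        conf = work.GetConformer(cids[i])
        xyz = np.asarray(conf.GetPositions(), dtype=float)
        if mol.n_atoms == no_h.GetNumAtoms():
            out.append(xyz[keep_idx])
        else:
            out.append(xyz[: mol.n_atoms])
    return out


# ---------------------------------------------------------------------------
# Gaussian shape overlay
# ---------------------------------------------------------------------------

def _alpha_for_radius(r: float) -> float:
    """Gaussian exponent matching the vdW sphere volume at amplitude 2.7."""
    vol = 4.0 / 3.0 * np.pi * r ** 3
    return np.pi * (GAUSSIAN_AMPLITUDE / vol) ** (2.0 / 3.0)


def _shape_params(elements: list[str]) -> np.ndarray:
    return np.array([_alpha_for_radius(vdw_radius(e)) for e in elements])


def gaussian_overlap(
    a_xyz: np.ndarray, a_alpha: np.ndarray, b_xyz: np.ndarray, b_alpha: np.ndarray
) -> float:
    """Closed-form overlap of two sums of Gaussians, amplitude 2.7 each."""
    if len(a_xyz) == 0 or len(b_xyz) == 0:
        return 0.0
    asum = a_alpha[:, None] + b_alpha[None, :]
    prod = a_alpha[:, None] * b_alpha[None, :]
    d2 = ((a_xyz[:, None, :] - b_xyz[None, :, :]) ** 2).sum(axis=2)
    terms = (
        GAUSSIAN_AMPLITUDE ** 2
        * (np.pi / asum) ** 1.5
        * np.exp(-prod / asum * d2)
    )
    return float(terms.sum())


@dataclass
class OverlayResult:
    """Rigid alignment of a candidate conformer onto a reference pose."""

    rotation: np.ndarray
    translation: np.ndarray
    shape_tanimoto: float
    color_tanimoto: float

    @property
    def combo(self) -> float:
        return self.shape_tanimoto + self.color_tanimoto

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return rigid_transform(self.rotation, self.translation, coords)


_PHARMACOPHORE_TYPES = ["donor", "acceptor", "anion", "cation", "aromatic", "hydrophobe"]


def pharmacophore_points(mol: Chem.Mol, xyz: np.ndarray) -> dict[str, np.ndarray]:
    """Typed pseudo-atom positions for color scoring (full-atom coordinates)."""
    pts: dict[str, list[np.ndarray]] = {t: [] for t in _PHARMACOPHORE_TYPES}
    for i in ligand_donor_atoms(mol):
        pts["donor"].append(xyz[i])
    for i in ligand_acceptor_atoms(mol):
        pts["acceptor"].append(xyz[i])
    for i in ligand_anion_atoms(mol):
        pts["anion"].append(xyz[i])
    for i in ligand_cation_atoms(mol):
        pts["cation"].append(xyz[i])
    for ring in ligand_aromatic_rings(mol):
        pts["aromatic"].append(xyz[ring].mean(axis=0))
    for i in ligand_apolar_carbons(mol):
        pts["hydrophobe"].append(xyz[i])
    return {t: (np.array(v) if v else np.zeros((0, 3))) for t, v in pts.items()}


def _color_tanimoto(
    ref_pts: dict[str, np.ndarray], cand_pts: dict[str, np.ndarray]
) -> float:
    alpha = _alpha_for_radius(COLOR_RADIUS)
    o_ab = o_aa = o_bb = 0.0
    for t in _PHARMACOPHORE_TYPES:
        a, b = ref_pts[t], cand_pts[t]
        aa = np.full(len(a), alpha)
        bb = np.full(len(b), alpha)
        o_ab += gaussian_overlap(a, aa, b, bb)
        o_aa += gaussian_overlap(a, aa, a, aa)
        o_bb += gaussian_overlap(b, bb, b, bb)
    if o_aa == 0.0 and o_bb == 0.0:
        return 1.0  # both featureless: vacuous identity (documented)
    denom = o_aa + o_bb - o_ab
    return o_ab / denom if denom > 0 else 0.0


def _principal_axes(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    centroid = xyz.mean(axis=0)
    centered = xyz - centroid
    cov = centered.T @ centered / max(1, len(xyz))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    degenerate = evals[order][1] < 1e-6  # collinear or single-point
    return centroid, axes, degenerate


def _start_rotations(ref_axes: np.ndarray, cand_axes: np.ndarray) -> list[np.ndarray]:
    """12 proper rotations mapping candidate principal axes onto the reference's."""
    perms = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    flips = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    out = []
    for p in perms:
        permuted = cand_axes[:, list(p)]
        for f in flips:
            axes = permuted * np.array(f)[None, :]
            if np.linalg.det(axes) < 0:
                axes = axes * -1
            out.append(ref_axes @ axes.T)
    return out


def overlay(
    candidate_conformer: np.ndarray,
    candidate_elements: list[str],
    reference: LigandMolecule,
    candidate_mol: Chem.Mol | None = None,
) -> OverlayResult:
    """Rigid overlay maximizing Gaussian volume overlap with the reference pose.

    Heavy atoms only drive the shape optimization; the color score is
    evaluated at the optimized transform when both molecular graphs are
    available (otherwise it is 0).  Local optimization is run from 12
    principal-axes starting orientations; degenerate (collinear) systems
    fall back to centroid alignment with a warning.
    """
    cand_xyz = np.asarray(candidate_conformer, dtype=float)
    heavy_mask = np.array([e.capitalize() != "H" for e in candidate_elements])
    cand_heavy = cand_xyz[heavy_mask]
    cand_alpha = _shape_params([e for e, m in zip(candidate_elements, heavy_mask) if m])

    ref_idx = [a.GetIdx() for a in reference.mol.GetAtoms() if a.GetAtomicNum() > 1]
    ref_heavy = reference.coords()[ref_idx]
    ref_alpha = _shape_params(
        [reference.mol.GetAtomWithIdx(i).GetSymbol() for i in ref_idx]
    )
    if len(cand_heavy) < 1 or len(ref_heavy) < 1:
        raise ContractError("overlay requires at least one heavy atom per molecule")

    o_aa = gaussian_overlap(ref_heavy, ref_alpha, ref_heavy, ref_alpha)
    o_bb = gaussian_overlap(cand_heavy, cand_alpha, cand_heavy, cand_alpha)

    ref_centroid, ref_axes, ref_degen = _principal_axes(ref_heavy)
    cand_centroid, cand_axes, cand_degen = _principal_axes(cand_heavy)
    degenerate = ref_degen or cand_degen or len(cand_heavy) < 3 or len(ref_heavy) < 3
    if degenerate and len(cand_heavy) >= 3:
        warnings.warn("degenerate principal axes; centroid-aligned starts only", stacklevel=2)

    centered = cand_heavy - cand_centroid

    def objective(x: np.ndarray) -> float:
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        moved = centered @ rot.T + ref_centroid + x[3:]
        return -gaussian_overlap(ref_heavy, ref_alpha, moved, cand_alpha)

    starts: list[np.ndarray]
    if degenerate:
        starts = [np.zeros(6)]
    else:
        starts = []
        for r0 in _start_rotations(ref_axes, cand_axes):
            starts.append(np.concatenate([Rotation.from_matrix(r0).as_rotvec(), np.zeros(3)]))

    best_val = np.inf
    best_x = np.zeros(6)
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 600, "xatol": 1e-4, "fatol": 1e-7})
        if res.fun < best_val:
            best_val = res.fun
            best_x = res.x

    rot = Rotation.from_rotvec(best_x[:3]).as_matrix()
    # full transform on original coordinates: R (x - c_cand) + c_ref + t
    translation = ref_centroid + best_x[3:] - rot @ cand_centroid
    o_ab = -best_val
    denom = o_aa + o_bb - o_ab
    shape_t = float(np.clip(o_ab / denom if denom > 0 else 0.0, 0.0, 1.0))

    color_t = 0.0
    if candidate_mol is not None:
        moved_full = rigid_transform(rot, translation, cand_xyz)
        cand_pts = pharmacophore_points(candidate_mol, moved_full)
        ref_pts = pharmacophore_points(reference.mol, reference.coords())
        color_t = float(np.clip(_color_tanimoto(ref_pts, cand_pts), 0.0, 1.0))

    return OverlayResult(rot, translation, shape_t, color_t)


def overlay_ligand(candidate: LigandMolecule, conformer: np.ndarray,
                   reference: LigandMolecule) -> OverlayResult:
    """Overlay one full-atom conformer of ``candidate`` onto ``reference``."""
    return overlay(conformer, candidate.elements(), reference, candidate_mol=candidate.mol)


# ---------------------------------------------------------------------------
# selection and placement
# ---------------------------------------------------------------------------

@dataclass
class DecoySet:
    """Up to three decoy complexes for one active, best combo first."""

    active_id: str
    decoys: list[ProteinLigandComplex]
    overlays: list[OverlayResult]

    def __post_init__(self) -> None:
        if len(self.decoys) > 3:
            raise ContractError("a decoy set holds at most 3 decoys")


def select_decoys(
    overlays: list[tuple[CandidateDecoy, OverlayResult]], k: int = 3
) -> list[tuple[CandidateDecoy, OverlayResult]]:
    """Top-``k`` candidates by TanimotoCombo, ties broken by name ascending."""
    ranked = sorted(overlays, key=lambda t: (-t[1].combo, t[0].molecule.name))
    return ranked[:k]


def place_into_pocket(
    protein: ProteinStructure,
    candidate: CandidateDecoy,
    transform: OverlayResult,
    conformer: np.ndarray | None = None,
) -> ProteinLigandComplex:
    """Place a candidate decoy into the pocket with the overlay transform.

    The returned complex carries ``meta['clash']`` (True when any ligand
    heavy atom approaches a protein heavy atom closer than 1.5 A) and
    ``meta['min_contact_distance']``; the caller decides whether to keep
    clashing placements.
    """
    validate_rotation(transform.rotation)
    xyz = conformer if conformer is not None else candidate.conformers[0]
    moved = transform.apply(np.asarray(xyz, dtype=float))
    lig = candidate.molecule.with_coords(moved)
    prot_heavy = protein.heavy_coords()
    lig_heavy = lig.coords(heavy_only=True)
    dmin = float(
        np.sqrt(((prot_heavy[:, None, :] - lig_heavy[None, :, :]) ** 2).sum(axis=2)).min()
    )
    return ProteinLigandComplex(
        protein=protein,
        ligand=lig,
        label="decoy",
        meta={"clash": dmin < CLASH_DISTANCE, "min_contact_distance": dmin},
    )


def build_decoy_set(
    active_complex: ProteinLigandComplex,
    pool: list[LigandMolecule],
    n_conformers: int = 50,
    seed: int = 0,
    windows: MatchWindows | None = None,
    rules: DruglikeRules | None = None,
    k: int = 3,
) -> DecoySet:
    """End-to-end decoy pipeline for one active complex.

    Property matching -> conformers -> best-conformer overlay per candidate
    -> top-k by combo -> placement.  Fewer than ``k`` decoys are returned
    when fewer candidates pass.
    """
    active = active_complex.ligand
    candidates = match_properties(active, pool, windows, rules)
    scored: list[tuple[CandidateDecoy, OverlayResult, np.ndarray]] = []
    for cand in candidates:
        try:
            confs = gen_conformers(cand.molecule, n_conformers, seed)
        except StructureError:
            continue
        cand.conformers = confs
        best: tuple[OverlayResult, np.ndarray] | None = None
        for conf in confs:
            ov = overlay_ligand(cand.molecule, conf, active)
            if best is None or ov.combo > best[0].combo:
                best = (ov, conf)
        if best is not None:
            scored.append((cand, best[0], best[1]))
    chosen = select_decoys([(c, o) for c, o, _ in scored], k=k)
    conf_of = {id(c): x for c, _, x in scored}
    decoys, overlays = [], []
    for cand, ov in chosen:
        cplx = place_into_pocket(active_complex.protein, cand, ov, conf_of[id(cand)])
        decoys.append(cplx)
        overlays.append(ov)
    return DecoySet(active_id=active_complex.complex_id, decoys=decoys, overlays=overlays)
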
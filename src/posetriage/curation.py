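"""Dataset-construction filters and asymmetric-unit copy augmentation.

Training actives are restricted to drug-like ligands bound in well-determined
X-ray structures: entries must be X-ray diffraction, strictly better than
2.5 A resolution, and contain a protein polymer.  Ligands pass data-driven
property windows plus an exclusion list of common biological ligands
(nucleotides, sugars, lipids, cofactors) that are abundant in structural
databases but are not the intended domain of a screening classifier.

When an asymmetric unit holds several copies of the same complex, every copy
is kept as a separate training instance (coordinate noise augmentation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .complex_io import (
    LigandMolecule,
    ProteinLigandComplex,
    ProteinStructure,
    Residue,
)
from .errors import ContentError, ContractError


@dataclass
class EntryMetadata:
    """Structure-level metadata used by the entry filter."""

    experimental_method: str
    resolution: float | None
    polymer_types: set[str]
    ligand_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ContractError("resolution must be positive when present")
        self.polymer_types = set(self.polymer_types)


@dataclass
class FilterReport:
    """Machine-readable pass/fail decision for one curation stage."""

    decision: str
    reasons: list[str]
    stage: str

    def __post_init__(self) -> None:
        if self.decision not in ("pass", "fail"):
            raise ContractError("decision must be pass or fail")
        if self.decision == "fail" and not self.reasons:
            raise ContractError("fail reports must carry at least one reason")

    @property
    def passed(self) -> bool:
        return self.decision == "pass"

    def to_json(self, source_id: str = "") -> str:
        d = asdict(self)
        if source_id:
            d["source_id"] = source_id
        return json.dumps(d, sort_keys=True)


RESOLUTION_CUTOFF = 2.5  # strict: exactly 2.5 A fails


def filter_entry(meta: EntryMetadata) -> FilterReport:
    """Entry-level filter: X-ray method, resolution < 2.5 A (strict), protein polymer."""
    reasons: list[str] = []
    if meta.experimental_method.strip().lower().replace("-", " ") not in (
        "x ray diffraction",
        "xray diffraction",
    ):
        reasons.append("method")
    if meta.resolution is None:
        reasons.append("missing_resolution")
    elif not meta.resolution < RESOLUTION_CUTOFF:
        reasons.append("resolution")
    if "Protein" not in meta.polymer_types:
        reasons.append("polymer_type")
    return FilterReport("fail" if reasons else "pass", reasons, "entry")


#: Component codes for common biological ligands excluded from training.
BIOLOGICAL_LIGANDS: frozenset[str] = frozenset({
    # nucleotides and analogues
    "ATP", "ADP", "AMP", "ANP", "GTP", "GDP", "GMP", "GNP", "UTP", "UDP",
    "UMP", "CTP", "CDP", "TTP", "DTP", "APC",
    # mono/oligosaccharides
    "GLC", "BGC", "GAL", "MAN", "BMA", "FUC", "XYS", "NAG", "NDG", "SIA",
    "MAL", "SUC", "TRE", "LAT",
    # lipids / fatty acids / detergents
    "PLM", "MYR", "OLA", "OLB", "STE", "PEE", "PCW", "LPE", "DGA",
    # cofactors and prosthetic groups
    "NAD", "NAI", "NAP", "NDP", "FAD", "FMN", "HEM", "HEC", "SF4", "FES",
    "PLP", "TPP", "COA", "ACO", "SAM", "SAH", "B12", "BTN", "FOL", "H4B",
    # cryoprotectants / buffer components frequently modelled
    "GOL", "EDO", "PEG", "PG4", "MPD", "DMS", "SO4", "PO4", "ACT", "CIT",
})

ALLOWED_ELEMENTS: frozenset[str] = frozenset(
    {"C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H"}
)


@dataclass
class DruglikeRules:
    """Serializable drug-likeness windows applied to training ligands.

    Defaults are a documented reconstruction of "drug-like" intent: MW
    150-600 Da, 12-45 heavy atoms, |net charge| <= 2, <= 12 rotatable bonds,
    organic elements only, and a named exclusion list of biological ligands.
    """

    mw_min: float = 150.0
    mw_max: float = 600.0
    heavy_min: int = 12
    heavy_max: int = 45
    max_abs_charge: int = 2
    max_rotatable: int = 12
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS
    blacklist: frozenset[str] = BIOLOGICAL_LIGANDS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_elements"] = sorted(self.allowed_elements)
        d["blacklist"] = sorted(self.blacklist)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DruglikeRules":
        d = dict(d)
        if "allowed_elements" in d:
            d["allowed_elements"] = frozenset(d["allowed_elements"])
        if "blacklist" in d:
            d["blacklist"] = frozenset(d["blacklist"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "DruglikeRules":
        return cls.from_dict(json.loads(Path(path).read_text()))


def filter_ligand_druglike(
    lig: LigandMolecule, rules: DruglikeRules | None = None
) -> FilterReport:
    """Drug-likeness filter for one ligand under a (serializable) rule set."""
    rules = rules or DruglikeRules()
    reasons: list[str] = []
    if lig.name.upper() in rules.blacklist:
        reasons.append("blacklist")
    try:
        mol = Chem.RemoveHs(lig.mol)
        mw = Descriptors.MolWt(lig.mol)
        heavy = mol.GetNumHeavyAtoms()
        charge = Chem.GetFormalCharge(mol)
        rotors = rdMolDescriptors.CalcNumRotatableBonds(mol)
        elements = {a.GetSymbol() for a in lig.mol.GetAtoms()}
    except Exception:
        return FilterReport("fail", reasons + ["descriptor_error"], "ligand")
    if not (rules.mw_min <= mw <= rules.mw_max):
        reasons.append("molecular_weight")
    if not (rules.heavy_min <= heavy <= rules.heavy_max):
        reasons.append("heavy_atoms")
    if abs(charge) > rules.max_abs_charge:
        reasons.append("formal_charge")
    if rotors > rules.max_rotatable:
        reasons.append("rotatable_bonds")
    if not elements <= rules.allowed_elements:
        reasons.append("element")
    return FilterReport("fail" if reasons else "pass", reasons, "ligand")


def filter_complex_quality(cplx: ProteinLigandComplex) -> FilterReport:
    """Metadata-driven model-quality checks on the assembled complex.

    Density-based validation is out of reach without maps; instead the
    checks that can be made from coordinates alone are applied: partially
    occupied ligand atoms fail, as does a ligand with fewer resolved heavy
    atoms than its connection table demands (both symptoms of a poorly
    determined ligand).
    """
    reasons: list[str] = []
    occ = cplx.meta.get("ligand_occupancies")
    if occ is not None and any(o < 1.0 for o in occ):
        reasons.append("partial_occupancy")
    expected = cplx.meta.get("expected_heavy_atoms")
    if expected is not None and cplx.ligand.n_heavy < expected:
        reasons.append("missing_atoms")
    return FilterReport("fail" if reasons else "pass", reasons, "complex")


def curate_complex(
    meta: EntryMetadata,
    cplx: ProteinLigandComplex,
    rules: DruglikeRules | None = None,
) -> list[FilterReport]:
    """All three curation stages; the complex passes iff every stage passes."""
    return [
        filter_entry(meta),
        filter_ligand_druglike(cplx.ligand, rules),
        filter_complex_quality(cplx),
    ]


def augment_copies(
    protein: ProteinStructure, ligand_template: LigandMolecule, label: str = "active"
) -> list[ProteinLigandComplex]:
    """One complex per asymmetric-unit copy of the cognate ligand.

    Copies are identified as non-polymer residues whose name matches the
    template; each copy's coordinates are transferred onto the template
    graph by atom order (source files are expected to repeat the component
    with a consistent atom layout).  All copies share the protein and
    ``source_id``; ``copy_index`` runs 0..n-1 in residue order.
    """
    name = ligand_template.name.upper()
    copies: list[Residue] = [
        r for r in protein.residues(polymer_only=False)
        if not any(a.is_polymer for a in r.atoms) and r.name.upper() == name
    ]
    if not copies:
        raise ContentError(f"no copy of ligand {ligand_template.name!r} in structure")
    protein_only = ProteinStructure(
        [a for a in protein.atoms if (a.chain_id, a.residue_number, a.residue_name) not in
         {c.key for c in copies}],
        source_id=protein.source_id,
    )
    out: list[ProteinLigandComplex] = []
    for idx, res in enumerate(sorted(copies, key=lambda r: (r.chain_id, r.number))):
        heavy = res.heavy_coords()
        if heavy.shape[0] != ligand_template.n_heavy:
            raise ContentError(
                f"copy {idx}: {heavy.shape[0]} heavy atoms != template {ligand_template.n_heavy}"
            )
        lig = ligand_template.with_coords(_map_heavy_coords(ligand_template, heavy))
        out.append(
            ProteinLigandComplex(
                protein=protein_only,
                ligand=lig,
                label=label,
                copy_index=idx,
                complex_id=f"{protein.source_id}_{ligand_template.name}_{idx}",
                meta={"ligand_occupancies": [a.occupancy for a in res.atoms]},
            )
        )
    return out


def _map_heavy_coords(template: LigandMolecule, heavy: np.ndarray) -> np.ndarray:
    """Full-atom coordinate array with heavy atoms replaced in graph order."""
    if template.has_pose:
        xyz = template.coords().copy()
    else:
        xyz = np.zeros((template.n_atoms, 3))
    j = 0
    for i, atom in enumerate(template.mol.GetAtoms()):
        if atom.GetAtomicNum() > 1:
            xyz[i] = heavy[j]
            j += 1
    return xyz


def write_reports_jsonl(
    reports: list[tuple[str, FilterReport]], path: str | Path
) -> None:
    """Emit (source_id, report) pairs as JSON lines."""
    with open(path, "w") as fh:
        for source_id, rep in reports:
            fh.write(rep.to_json(source_id) + "\n")
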
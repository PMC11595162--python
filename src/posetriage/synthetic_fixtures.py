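"""Synthetic inputs for every pipeline stage: toy protein-ligand complexes,
labeled feature tables with planted signal and cluster structure, and
benchmark-shaped score sets (81 targets, 30-40 actives, 800-1200 decoys
per target by default).

The generators are fully deterministic per seed and emit the same formats
the pipeline consumes.  They make no claim of biophysical realism: they
exercise code paths and statistical contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .complex_io import (
    AtomRecord,
    LigandMolecule,
    ProteinLigandComplex,
    ProteinStructure,
)
from .errors import ContractError
from .screening_metrics import ScoreTable
from .classifier import LabeledDataset

import pandas as pd

#: Default toy ligand: 4-phenylphenol (passes the default drug-likeness filters).
DEFAULT_LIGAND_SMILES = "Oc1ccc(-c2ccccc2)cc1"


@dataclass
class FixtureSpec:
    """All generator knobs in one place; every generator takes a seed."""

    seed: int = 0
    # toy-complex geometry
    n_residues: int = 44
    pocket_clearance: float = 3.0   # A between ligand extent and residue shells
    geometry: str = "cage"          # "cage" (enclosed) or "bowl" (open surface)
    ligand_smiles: str = DEFAULT_LIGAND_SMILES
    # feature-table parameters
    n_active: int = 1000
    n_decoy: int = 1000
    n_clusters: int = 10
    n_informative: int = 5
    n_noise: int = 45
    effect_size: float = 3.0
    confound: bool = False
    # benchmark parameters
    n_targets: int = 81
    actives_range: tuple[int, int] = (30, 40)
    decoys_range: tuple[int, int] = (800, 1200)
    separation: float = 2.0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ContractError("effect_size must be >= 0")
        if self.actives_range[0] > self.actives_range[1]:
            raise ContractError("invalid actives range")
        if self.decoys_range[0] > self.decoys_range[1]:
            raise ContractError("invalid decoys range")


def _sphere_points(n: int, hemisphere: bool = False) -> np.ndarray:
    """Deterministic near-uniform directions (lower hemisphere only for bowls)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    if hemisphere:
        z = -(i + 0.5) / n           # z in (-1, 0): open top
    else:
        z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _embedded_ligand(smiles: str, seed: int) -> LigandMolecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ContractError(f"bad ligand SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ContractError("ligand embedding failed")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    mol = Chem.RemoveHs(mol)
    xyz = np.asarray(mol.GetConformer().GetPositions())
    xyz = xyz - xyz.mean(axis=0)
    conf = mol.GetConformer()
    for k in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(k, xyz[k].tolist())
    return LigandMolecule(mol, name="TOY")


def _alanine_at(point: np.ndarray, inward: np.ndarray, chain: str, number: int) -> list[AtomRecord]:
    """A free-standing alanine residue at ``point`` with CB pointing inward."""
    u = inward / np.linalg.norm(inward)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(u)))] = 1.0
    t1 = np.cross(u, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    ca = point
    atoms = [
        ("N", "N", ca + 1.46 * t1),
        ("CA", "C", ca),
        ("C", "C", ca + 1.52 * t2),
        ("O", "O", ca + 1.52 * t2 - 1.23 * u),
        ("CB", "C", ca + 1.53 * u),
    ]
    return [
        AtomRecord(element=el, name=nm, residue_name="ALA", residue_number=number,
                   chain_id=chain, coords=xyz)
        for nm, el, xyz in atoms
    ]


def make_toy_complex(spec: FixtureSpec | None = None) -> ProteinLigandComplex:
    """A shell of alanine residues enclosing a centred small-molecule pose.

    ``geometry='cage'`` surrounds the ligand (high enclosure);
    ``geometry='bowl'`` keeps only the lower hemisphere (open surface, low
    enclosure).  The shell radius adapts to the ligand so the fixture is
    clash-free and featurizable with zero sentinels.
    """
    spec = spec or FixtureSpec()
    lig = _embedded_ligand(spec.ligand_smiles, spec.seed)
    xyz = lig.coords(heavy_only=True)
    extent = float(np.linalg.norm(xyz, axis=1).max())
    radius = extent + spec.pocket_clearance + 1.53  # CB sits 1.53 A inside CA shell

    hemisphere = spec.geometry == "bowl"
    n_res = spec.n_residues // 2 if hemisphere else spec.n_residues
    dirs = _sphere_points(n_res, hemisphere=hemisphere)
    atoms: list[AtomRecord] = []
    for i, d in enumerate(dirs):
        atoms.extend(_alanine_at(d * radius, -d, "A", i + 1))
    protein = ProteinStructure(atoms, source_id=f"toy_{spec.geometry}_{spec.seed}")
    return ProteinLigandComplex(
        protein=protein, ligand=lig, label="active",
        complex_id=f"toy_{spec.geometry}_{spec.seed}",
    )


def make_feature_table(spec: FixtureSpec | None = None) -> LabeledDataset:
    """Labeled feature matrix with planted class signal and cluster structure.

    Informative features are unit-variance normals whose class means differ
    by ``effect_size``; noise features are class-independent.  In confound
    mode the class signal is carried by cluster membership instead: labels
    follow the cluster's parity and one feature encodes a cluster-specific
    offset, so grouped CV (new clusters in test) sees no generalizable
    signal while row-random CV does — the leakage scenario grouped folds
    exist to prevent.
    """
    spec = spec or FixtureSpec()
    if spec.n_informative + spec.n_noise < 1:
        raise ContractError("need at least one feature")
    n = spec.n_active + spec.n_decoy
    if spec.n_clusters > n:
        raise ContractError("more clusters than rows")
    rng = np.random.default_rng(spec.seed)

    if spec.confound:
        clusters = rng.integers(0, spec.n_clusters, size=n)
        labels = (clusters % 2).astype(int)
        cluster_offset = rng.normal(0.0, 3.0, size=spec.n_clusters)
        n_feat = spec.n_informative + spec.n_noise
        X = rng.normal(0.0, 1.0, size=(n, n_feat))
        X[:, 0] += cluster_offset[clusters]  # cluster fingerprint, not class signal
    else:
        labels = np.array([1] * spec.n_active + [0] * spec.n_decoy)
        clusters = rng.integers(0, spec.n_clusters, size=n)
        n_feat = spec.n_informative + spec.n_noise
        X = rng.normal(0.0, 1.0, size=(n, n_feat))
        X[:, : spec.n_informative] += spec.effect_size * labels[:, None]

    names = [f"signal_{i}" for i in range(spec.n_informative)] + [
        f"noise_{i}" for i in range(spec.n_noise)
    ]
    ids = [f"cplx_{i:05d}" for i in range(n)]
    features = pd.DataFrame(X, index=pd.Index(ids, name="complex_id"), columns=names)
    return LabeledDataset(
        features,
        pd.Series(labels, index=features.index, name="label"),
        pd.Series(clusters, index=features.index, name="cluster_id"),
    )


@dataclass
class SyntheticBenchmark:
    """Per-target score tables for one or more named scoring methods."""

    tables: dict[str, list[ScoreTable]]  # method -> one table per target

    def methods(self) -> list[str]:
        return sorted(self.tables)


def make_benchmark(
    spec: FixtureSpec | None = None,
    methods: dict[str, float] | None = None,
) -> SyntheticBenchmark:
    """Benchmark-shaped score sets with controllable score separation.

    Decoy scores are standard normal; active scores are shifted by a
    per-method separation scaled by a per-target jitter (shared across
    methods, so per-target difficulty is paired).  ``methods`` maps a
    method name to its separation multiplier; the default provides one
    method at the spec's separation.
    """
    spec = spec or FixtureSpec()
    if spec.n_targets < 1:
        raise ContractError("n_targets must be >= 1")
    methods = methods or {"method": 1.0}
    rng = np.random.default_rng(spec.seed)
    tables: dict[str, list[ScoreTable]] = {m: [] for m in methods}
    for t in range(spec.n_targets):
        n_act = int(rng.integers(spec.actives_range[0], spec.actives_range[1] + 1))
        n_dec = int(rng.integers(spec.decoys_range[0], spec.decoys_range[1] + 1))
        jitter = float(rng.lognormal(mean=0.0, sigma=0.4))
        target_id = f"T{t:03d}"
        labels = ["active"] * n_act + ["decoy"] * n_dec
        ids = [f"L{i:05d}" for i in range(n_act + n_dec)]
        for m, quality in methods.items():
            shift = spec.separation * quality * jitter
            scores = np.concatenate([
                rng.normal(shift, 1.0, size=n_act),
                rng.normal(0.0, 1.0, size=n_dec),
            ])
            tables[m].append(ScoreTable.from_records(
                target_id, list(zip(ids, scores.tolist(), labels))
            ))
    return SyntheticBenchmark(tables)
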
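"""Sequence clustering for leakage-safe cross-validation folds.

Homologous proteins carry near-identical pockets; letting them straddle a
train/test split inflates apparent performance.  Sequences are therefore
clustered by global-alignment identity with a greedy centroid scheme
(length-descending, deterministic), folds are whole clusters
(leave-one-cluster-out), and training targets similar to any benchmark
target can be excluded outright.

An adapter accepts an externally produced id -> cluster table (two-column
TSV) so output from a dedicated clustering tool can be substituted verbatim.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO

from .errors import ContentError, ContractError

_VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence (standard 20 letters + X, length >= 20)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 20:
            raise ContractError(f"{self.id}: sequence shorter than 20 residues")
        bad = set(seq) - _VALID_LETTERS
        if bad:
            raise ContractError(f"{self.id}: invalid letters {sorted(bad)}")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment identity: matches / alignment length (symmetric)."""
    if not a.sequence or not b.sequence:
        raise ContentError("cannot align an empty sequence")
    aligner = _make_aligner()
    alignment = aligner.align(a.sequence, b.sequence)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


@dataclass
class ClusterAssignment:
    """id -> cluster index mapping with contiguous indices from 0."""

    mapping: dict[str, int]
    n_clusters: int

    def __post_init__(self) -> None:
        used = set(self.mapping.values())
        if used and used != set(range(self.n_clusters)):
            raise ContractError("cluster indices must be contiguous from 0")

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.mapping.items() if c == cluster]


def cluster_sequences(
    seqs: list[SequenceRecord], threshold: float = 0.3
) -> ClusterAssignment:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed longest first (id ascending on ties); each joins
    the earliest-founded centroid with identity >= threshold, else founds a
    new cluster.  Deterministic.
    """
    if not seqs:
        raise ContractError("need at least one sequence")
    ordered = sorted(seqs, key=lambda s: (-len(s.sequence), s.id))
    centroids: list[SequenceRecord] = []
    mapping: dict[str, int] = {}
    for rec in ordered:
        assigned = None
        for ci, cen in enumerate(centroids):
            if pairwise_identity(rec, cen) >= threshold:
                assigned = ci
                break
        if assigned is None:
            assigned = len(centroids)
            centroids.append(rec)
        mapping[rec.id] = assigned
    return ClusterAssignment(mapping, len(centroids))


@dataclass
class FoldPlan:
    """A list of (train ids, test ids) pairs partitioning the dataset."""

    folds: list[tuple[list[str], list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        all_ids: set[str] = set()
        seen_test: set[str] = set()
        for train, test in self.folds:
            if set(train) & set(test):
                raise ContractError("train and test overlap within a fold")
            if seen_test & set(test):
                raise ContractError("test sets across folds must be disjoint")
            seen_test |= set(test)
            all_ids |= set(train) | set(test)
        if self.folds and seen_test != all_ids:
            raise ContractError("union of test sets must cover every id")

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


def make_locc_folds(assignment: ClusterAssignment) -> FoldPlan:
    """Leave-one-cluster-out folds: fold i tests cluster i, trains on the rest."""
    if assignment.n_clusters < 2:
        raise ContentError("cannot form held-out folds from a single cluster")
    ids_by_cluster = [assignment.members(c) for c in range(assignment.n_clusters)]
    folds = []
    for c in range(assignment.n_clusters):
        test = sorted(ids_by_cluster[c])
        train = sorted(i for cc, ids in enumerate(ids_by_cluster) if cc != c for i in ids)
        folds.append((train, test))
    return FoldPlan(folds)


def make_grouped_kfolds(assignment: ClusterAssignment, k: int, seed: int = 0) -> FoldPlan:
    """k folds of whole clusters (clusters shuffled deterministically by seed).

    A coarser alternative to leave-one-cluster-out when the cluster count is
    large; no cluster ever spans train and test.
    """
    import numpy as np

    if k < 2 or k > assignment.n_clusters:
        raise ContractError("k must be in [2, n_clusters]")
    rng = np.random.default_rng(seed)
    clusters = rng.permutation(assignment.n_clusters)
    groups = [clusters[i::k] for i in range(k)]
    folds = []
    for g in groups:
        test_set = {int(c) for c in g}
        test = sorted(i for c in test_set for i in assignment.members(c))
        train = sorted(
            i for c in range(assignment.n_clusters) if c not in test_set
            for i in assignment.members(c)
        )
        folds.append((train, test))
    return FoldPlan(folds)


@dataclass
class RemovalReport:
    removed: list[tuple[str, str, float]]  # (training id, benchmark id, identity)


def exclude_similar(
    training: list[SequenceRecord],
    benchmark: list[SequenceRecord],
    threshold: float,
) -> tuple[list[SequenceRecord], RemovalReport]:
    """Remove every training sequence with identity >= threshold to ANY benchmark sequence."""
    kept: list[SequenceRecord] = []
    removed: list[tuple[str, str, float]] = []
    for rec in training:
        hit = None
        for b in benchmark:
            ident = pairwise_identity(rec, b)
            if ident >= threshold:
                hit = (rec.id, b.id, ident)
                break
        if hit is None:
            kept.append(rec)
        else:
            removed.append(hit)
    return kept, RemovalReport(removed)


# ---------------------------------------------------------------------------
# file adapters
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ContentError(f"no FASTA records in {path}")
    return records


def write_assignment_tsv(assignment: ClusterAssignment, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for seq_id in sorted(assignment.mapping):
            w.writerow([seq_id, assignment.mapping[seq_id]])


def read_assignment_tsv(path: str | Path) -> ClusterAssignment:
    """Adapter for externally produced id -> cluster tables (two-column TSV).

    Arbitrary cluster labels are remapped to contiguous indices in order of
    first appearance.
    """
    mapping: dict[str, int] = {}
    relabel: dict[str, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ContentError(f"expected two columns, got {row!r}")
            seq_id, label = row
            if label not in relabel:
                relabel[label] = len(relabel)
            mapping[seq_id] = relabel[label]
    if not mapping:
        raise ContentError(f"no assignments in {path}")
    return ClusterAssignment(mapping, len(relabel))
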
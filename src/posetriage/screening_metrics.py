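"""Per-target ranking, enrichment factors, ROC, and the paired-method
binomial comparison used for virtual-screening benchmarks.

The enrichment factor at a fraction f is the number of actives found in the
top ceil(f * N) of the ranked list divided by the number expected under
random ranking (n_actives * n_selected / N).  Methods are compared per
target by EF at 1%: near ties (absolute EF difference below 3) are removed
and the remaining wins go into an exact two-sided binomial test at p = 1/2
(minlike convention: the two-sided p sums all outcome probabilities not
exceeding that of the observed count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ContentError, ContractError


@dataclass
class ScoreTable:
    """Ranked-screening input: one target's ligand scores with labels."""

    target_id: str
    entries: pd.DataFrame  # columns: ligand_id, score, label

    def __post_init__(self) -> None:
        required = {"ligand_id", "score", "label"}
        if not required <= set(self.entries.columns):
            raise ContractError(f"score table needs columns {sorted(required)}")
        if self.entries["ligand_id"].duplicated().any():
            raise ContractError("ligand ids must be unique within a target")
        bad = ~self.entries["label"].isin(["active", "decoy"])
        if bad.any():
            raise ContractError("labels must be 'active' or 'decoy'")

    @property
    def n_total(self) -> int:
        return len(self.entries)

    @property
    def n_actives(self) -> int:
        return int((self.entries["label"] == "active").sum())

    @classmethod
    def from_records(cls, target_id, records) -> "ScoreTable":
        return cls(target_id, pd.DataFrame(records, columns=["ligand_id", "score", "label"]))


def rank(table: ScoreTable) -> pd.DataFrame:
    """Entries sorted by score descending, ties broken by ligand_id ascending."""
    scores = table.entries["score"]
    if scores.isna().any():
        bad = table.entries.loc[scores.isna(), "ligand_id"].iloc[0]
        raise ContentError(f"NaN score for ligand {bad!r}")
    if not np.all(np.isfinite(scores)):
        bad = table.entries.loc[~np.isfinite(scores), "ligand_id"].iloc[0]
        raise ContentError(f"non-finite score for ligand {bad!r}")
    return table.entries.sort_values(
        ["score", "ligand_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class EnrichmentResult:
    """EF at a top fraction; ef = actives_found / actives_expected."""

    fraction: float
    n_selected: int
    actives_found: int
    actives_expected: float
    ef: float


def ef_at(table: ScoreTable, fraction: float = 0.01) -> EnrichmentResult:
    """Enrichment factor of actives in the top ``fraction`` of the ranked list.

    The selection size is ceil(fraction * N).  With 30 actives among 1000
    entries, random ranking puts 0.3 actives in the top 10, so finding 3
    there is an enrichment factor of 10.
    """
    if not (0.0 < fraction <= 1.0):
        raise ContractError("fraction must lie in (0, 1]")
    n_act = table.n_actives
    if n_act == 0:
        raise ContentError(f"target {table.target_id}: no actives, EF undefined")
    ranked = rank(table)
    n_total = table.n_total
    n_sel = math.ceil(fraction * n_total)
    found = int((ranked["label"].iloc[:n_sel] == "active").sum())
    expected = n_act * n_sel / n_total
    return EnrichmentResult(fraction, n_sel, found, expected, found / expected)


def roc(table: ScoreTable) -> tuple[pd.DataFrame, float]:
    """ROC curve points and AUC (Mann-Whitney; ties count one half)."""
    y = (table.entries["label"] == "active").astype(int).to_numpy()
    s = table.entries["score"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ContentError("ROC requires both labels")
    fpr, tpr, thr = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(roc_auc_score(y, s))


@dataclass
class ComparisonResult:
    """Paired EF1% comparison of two methods across targets."""

    per_target: pd.DataFrame  # columns: target_id, ef_a, ef_b
    n_near_ties: int
    n_a_wins: int
    n_b_wins: int
    p_value: float
    p_defined: bool = True
    near_tie_threshold: float = 3.0


def compare_methods(
    efs_a: dict[str, float],
    efs_b: dict[str, float],
    near_tie: float = 3.0,
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Near-tie-filtered sign comparison with an exact binomial test.

    Targets with |ef_a - ef_b| < ``near_tie`` are excluded; the remaining
    wins are tested against Binomial(n, 1/2).  The two-sided p-value follows
    the minlike convention (sum of point probabilities <= that of the
    observed count); a one-sided test is available via ``alternative``.
    """
    if set(efs_a) != set(efs_b):
        raise ContractError("both methods must cover the same target set")
    rows = [(t, efs_a[t], efs_b[t]) for t in sorted(efs_a)]
    per_target = pd.DataFrame(rows, columns=["target_id", "ef_a", "ef_b"])
    diff = per_target["ef_a"] - per_target["ef_b"]
    near = (diff.abs() < near_tie).sum()
    a_wins = int((diff >= near_tie).sum())
    b_wins = int((diff <= -near_tie).sum())
    n = a_wins + b_wins
    if n == 0:
        return ComparisonResult(per_target, int(near), 0, 0, float("nan"),
                                p_defined=False, near_tie_threshold=near_tie)
    p = binomtest(a_wins, n, 0.5, alternative=alternative).pvalue
    return ComparisonResult(per_target, int(near), a_wins, b_wins, float(p),
                            near_tie_threshold=near_tie)


def read_score_table_csv(path, target_id: str | None = None) -> list[ScoreTable]:
    """Score tables from CSV with columns target_id, ligand_id, score, label."""
    df = pd.read_csv(path)
    required = {"target_id", "ligand_id", "score", "label"}
    if not required <= set(df.columns):
        raise ContentError(f"score CSV needs columns {sorted(required)}")
    out = []
    for tid, grp in df.groupby("target_id", sort=True):
        if target_id is not None and tid != target_id:
            continue
        out.append(ScoreTable(str(tid), grp[["ligand_id", "score", "label"]].reset_index(drop=True)))
    if not out:
        raise ContentError("no matching targets in score CSV")
    return out


def write_score_tables_csv(tables: list[ScoreTable], path) -> None:
    frames = []
    for t in tables:
        df = t.entries.copy()
        df.insert(0, "target_id", t.target_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
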
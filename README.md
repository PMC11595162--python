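# posetriage

Rescoring of docked protein–ligand poses to suppress false positives in
structure-based virtual screening.

Docking campaigns against ultra-large libraries routinely report single-digit
hit rates: the scoring functions that rank billions of poses are fast but
poor at telling a genuine binder from a geometrically plausible impostor.
`posetriage` implements the complementary step a medicinal-chemistry team
runs *after* docking and *before* purchasing compounds: a supervised
classifier that rescores each pose between 0 (decoy-like) and 1
(active-like), trained on crystallographic actives against property-matched
decoy complexes so that it cannot win by trivial physicochemistry.

The package is a library first (the `posetriage.*` modules plus the short
scripts in `examples/`), with a thin `posetriage` command-line wrapper for
pipeline use.

## What it implements

* **Structure handling** (`complex_io`) — PDB/mmCIF proteins via gemmi,
  SDF/MOL2 ligands via RDKit, altloc collapse, rule-based polar-hydrogen
  assignment, pocket extraction.
* **Curation** (`curation`) — entry filters (X-ray, resolution < 2.5 Å,
  protein polymer), serializable drug-likeness windows with a biological
  ligand exclusion list, and asymmetric-unit copy augmentation.
* **Feature engine** (`feature_engine`) — 166 named descriptors in six
  families: ligand 2D topology, MMFF94 pose energy and conformational
  strain, typed interface contacts (hydrogen bonds, salt bridges,
  hydrophobic, π-stacking, cation-π, halogen bonds), buried unsatisfied
  polar groups, grid/ray pocket-shape measures, and SASA burial partitions
  (own deterministic Shrake–Rupley quadrature). Every feature is invariant
  under rigid motion of the complex.
* **Decoy builder** (`decoy_builder`) — property matching against a local
  candidate pool, ETKDG conformer ensembles, rigid alignment maximizing
  Gaussian volume overlap, and selection of the top 3 candidates by
  TanimotoCombo = shape Tanimoto + pharmacophore ("color") Tanimoto.
* **Sequence clustering** (`seq_cluster`) — global-alignment identity,
  greedy centroid clustering, leave-one-cluster-out fold plans, and
  exclusion of training targets similar to benchmark targets. An adapter
  accepts externally produced cluster tables verbatim.
* **Classifier** (`classifier`) — XGBoost binary model, grouped
  cross-validation with pooled out-of-fold metrics, seeded random search
  over (`n_estimators`, `max_depth`, `learning_rate`), and sequential
  backward floating feature selection (SBFS) maximizing the Matthews
  correlation coefficient,

  MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

* **Screening metrics** (`screening_metrics`) — deterministic ranking,
  enrichment factors

  EF_f = (actives found in top ⌈fN⌉) / (n_actives · ⌈fN⌉ / N),

  ROC/AUC, and a paired-method comparison that removes near ties
  (|ΔEF1%| < 3) and applies the exact two-sided binomial test.
* **Synthetic fixtures** (`synthetic_fixtures`) — seeded generators for toy
  pocketed complexes, labeled feature tables with planted signal or cluster
  confounding, and benchmark-shaped score sets (81 targets, 30–40 actives,
  800–1200 decoys per target).

## Worked example

The screening-metrics arithmetic on the canonical worked case — a target
with 30 actives and 970 decoys, where a scoring method places 3 actives in
its 10 top-ranked poses:

```python
from posetriage.screening_metrics import ScoreTable, ef_at

records = [(f"L{i}", float(1000 - i),
            "active" if i in (0, 4, 9) or i >= 973 else "decoy")
           for i in range(1000)]
res = ef_at(ScoreTable.from_records("demo", records), fraction=0.01)
print(res.n_selected, res.actives_found, res.actives_expected, res.ef)
# 10 3 0.3 10.0
```

Random ranking would put 0.3 actives in the top 10, so finding 3 is a
10-fold enrichment.

End-to-end, `python examples/05_benchmark_comparison.py` builds a synthetic
81-target benchmark for a strong and a weak method and prints:

```
median EF1%: strong 20.6, weak 9.3
near ties (|dEF1%| < 3): 18
wins: strong 62, weak 1
exact two-sided binomial p = 1.39e-17
```

i.e. after discarding the 18 targets where the two methods are within 3
EF1% units of each other, the strong method wins 62 of the remaining 63
targets — a pattern a fair coin would essentially never produce.

The other examples cover featurization (`01`), decoy building (`02`),
leakage-safe training (`03`, showing grouped CV AUC 0.248 vs row-random
0.658 on cluster-confounded data), and feature selection (`04`).

## Command line

```bash
posetriage fixtures --seed 1 --outdir fx       # synthetic inputs
posetriage train --data fx/features.csv --model-out model.json --n-folds 3
posetriage score --model model.json --data fx/features.csv --out scored.csv
posetriage ef --scores fx/scores_method_a.csv --out ef.json
posetriage compare --scores-a ... --scores-b ... --out cmp.json
```

Exit codes: 0 success, 2 contract error (bad arguments/schema), 3 content
error (valid input that cannot be processed). Every output embeds a
provenance block (seed, config hash, input digests).

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
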
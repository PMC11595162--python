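# Methods

This note documents the models, conventions, and numerical choices behind
`posetriage`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, with which defaults, and what the
synthetic test bed does and does not establish.

## The classification problem

The unit of analysis is a protein–ligand complex: one protein model and one
ligand pose in a shared Cartesian frame. Training complexes carry binary
labels — crystallographic actives are 1, constructed decoys are 0 — and the
classifier's output is the logistic score of a gradient-boosted tree
ensemble, read as "how much does this pose look like a deposited active
complex". Applied after docking, the score triages poses before compound
purchase; it is not a binding-affinity prediction.

## Structure model and protonation

Proteins are flattened to typed atom records (element, name, residue,
chain, coordinates, occupancy, altloc). Alternate locations are collapsed
to a single conformer — highest occupancy wins, ties go to the
lexicographically first tag — because every downstream feature assumes one
geometry. Waters and foreign heteroatoms are retained but flagged; polymer
sequences are derived from Cα-bearing standard residues.

Protonation is rule-based and pKa-free: protein donors receive idealized
hydrogens from per-residue templates (N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å;
sp2 donors in-plane, sp3 donors as staggered tripods; the neutral His
tautomer carries H on NE2), ligand carboxylic acids are deprotonated and
aliphatic amines protonated, then explicit polar hydrogens are added with
coordinates. The procedure is deterministic and idempotent; hydrogens whose
heavy neighbours are missing are skipped and counted. This is a documented
stand-in for a dedicated protonation engine — tautomer and pKa subtleties
are out of scope, and no claim is made that its output matches any external
tool.

## Curation

Entry-level filters demand X-ray diffraction, refinement resolution
strictly below 2.5 Å (exactly 2.5 fails), and a protein polymer. Ligand
drug-likeness windows default to MW 150–600 Da, 12–45 heavy atoms, |net
charge| ≤ 2, ≤ 12 rotatable bonds, organic elements only
({C,N,O,S,P,F,Cl,Br,I,H}), plus a named exclusion list of common biological
ligands (nucleotides, saccharides, lipids, cofactors, cryoprotectants).
These windows are a reconstruction of "drug-like" intent and are fully
overridable through a serialized rule set; they are not claimed to
reproduce any specific historical dataset size. Model-quality checks that
would need electron density are replaced by coordinate-level proxies:
partially occupied ligand atoms fail, as does a ligand with fewer resolved
heavy atoms than its connection table. When an asymmetric unit contains
several copies of the cognate complex, each copy becomes its own training
instance (coordinate-noise augmentation).

## The 166-feature registry

Exactly 166 descriptors in six families with fixed quotas — ligand 2D
topology (40), ligand energy (6), interface contacts (60), buried
unsatisfied polar atoms (10), pocket shape (20), SASA burial partitions
(30). The count and the family structure are the registry's contract; each
entry carries a name, units, and a one-line description, and the registry
version travels with every trained model so stale models are refused at
scoring time.

Key conventions:

* **SASA** is Shrake–Rupley quadrature with probe 1.4 Å, 960 points per
  atom on a Fibonacci spiral (deterministic — no random rotations), and a
  Bondi-class van der Waals radius table. Isolated-sphere areas agree with
  the closed form to well under 1 %; two-sphere systems are validated
  against the analytic spherical-cap formula.
* **Interface contacts** use explicit geometric criteria: hydrogen bond
  donor–acceptor ≤ 3.5 Å with D–H···A ≥ 120°; salt bridge: opposite formal
  charges, N/O pair ≤ 4.0 Å; hydrophobic: apolar C···C ≤ 4.5 Å (an apolar
  carbon is one with no N/O within covalent range, 1.65 Å); π-stacking:
  ring centroids ≤ 5.5 Å with interplanar angle ≤ 30° (parallel) or ≥ 60°
  (T-shaped); cation–π: charged N to centroid ≤ 6.0 Å; halogen bond:
  C–X···A with X ∈ {Cl, Br, I}, X···A ≤ 3.5 Å, angle ≥ 140°. All cutoffs
  are configurable; contact lists are sorted for bit-stable output.
* **Buried unsatisfied polar atoms**: a ligand N/O/S is buried when its
  complexed SASA falls below 0.1 Å² and unsatisfied when it participates in
  no hydrogen bond or salt bridge; counts are reported in five classes
  (donor/acceptor × N/O, plus S). Adding a partner at valid geometry can
  only decrease the counts.
* **Ligand strain** is MMFF94: pose energy minus the minimum over an
  ETKDG-embedded, MMFF-relaxed conformer ensemble (default 30 conformers,
  fixed seed). The ensemble is generated from the molecular graph alone, so
  strain is exactly invariant under rigid motion of the pose; it can dip
  marginally below zero within minimizer tolerance when the pose is itself
  the global minimum.
* **Pocket shape** is measured on a 0.6 Å grid in a canonical frame built
  from the ligand's principal axes (signs fixed by third moments): pocket
  volume counts protein-free voxels whose axis rays hit protein in ≥ 4 of 6
  directions; enclosure is the fraction of 240 rays from the ligand
  centroid that hit probe-expanded protein within 10 Å; depth is the
  deepest ligand atom inside the convex hull of the pocket residues. The
  canonical frame makes every ray- and grid-based quantity invariant under
  joint rigid transforms (verified to 1e-6 relative in the tests); the
  frame is ill-defined only for ligands with exactly symmetric inertia,
  which real drug-like molecules do not have.

Families fail independently: an error in one family writes NaN sentinels
for that family only, with the reason recorded, and sentinels are passed to
the tree learner as missing values.

## Decoy construction

Decoys answer a specific failure mode: a classifier trained on actives
versus *random* molecules learns physicochemistry, not recognition of good
poses. Candidates therefore must match the active within MW ± 25 Da,
logP ± 1.0, rotatable bonds ± 2, HBD/HBA ± 1, equal net charge, pass the
same drug-likeness filters as actives, and differ in graph from the active;
at most 50 candidates are kept, nearest first. Each candidate gets an ETKDG
conformer ensemble (MMFF-relaxed, deduplicated at 0.5 Å heavy-atom RMSD),
every conformer is rigidly aligned onto the active pose, and the top three
candidates by TanimotoCombo are placed into the pocket with the alignment
transform. Placement reports the minimum protein–ligand heavy-atom
distance and flags approaches below 1.5 Å as clashes; no energy
minimization is attempted — refinement beyond polar-hydrogen assignment is
an explicit non-goal.

The alignment objective is Gaussian volume overlap: the molecular density
is a **sum** of atom-centred Gaussians of amplitude p = 2.7 whose exponent
is set per element so an isolated atom's Gaussian integral equals its vdW
sphere volume. Overlaps are closed-form pairwise Gaussian products;
optimization runs Nelder–Mead over rotation + translation from 12
principal-axes starting orientations (3 cyclic axis permutations × 4 proper
sign flips), falling back to centroid alignment for degenerate (collinear
or < 3 heavy atom) systems. Shape Tanimoto is O_AB/(O_AA + O_BB − O_AB);
color Tanimoto applies the same formula over pharmacophore pseudo-atoms
(donor, acceptor, anion, cation, aromatic-ring centroid, hydrophobe; 1.0 Å
Gaussians, same-type overlaps only) at the shape-optimal transform. Two
molecules with no pharmacophore features at all score color 1.0 (vacuous
identity — preserves self-combo = 2); this corner case cannot occur for
carbon-containing molecules. The sum-of-Gaussians density omits the
hard-sphere overlap correction of more elaborate shape models; since both
O_AB and the self-overlaps use the same density, the Tanimoto ratio is
affected far less than the raw volumes, and the closed form tracks direct
grid integration to within 2 % on the tested systems.

## Leakage-safe folds

Sequence identity is global alignment (match +1, mismatch −1, gap open −10,
extend −0.5) with identity = matches / alignment columns. Clustering is
greedy centroid assignment, longest sequence first (id as tie-break): a
sequence joins the earliest centroid with identity at or above the
threshold, else founds a new cluster. The default threshold is 0.3 — a
conservative choice below the twilight zone of sequence similarity; it is a
package default, not a claim about any external clustering run. Folds are
whole clusters (leave-one-cluster-out, or clusters dealt into k groups);
the test suite brute-forces the zero-leakage guarantee on fixtures. An
adapter ingests external id → cluster tables so a dedicated clustering tool
can replace the internal one verbatim.

## Classifier and selection

The model is binary XGBoost (logistic objective, histogram tree method
with 64 bins, one thread, explicit seeds — bit-stable across runs). No
feature scaling is applied: trees are scale-invariant. Cross-validation
scores every row exactly once out-of-fold; folds whose training half lacks
a class are skipped with a warning. Both pooled (concatenated out-of-fold)
and per-fold metrics are reported, since averaging conventions differ
between studies; the pooled numbers are used as objectives. A score of
exactly 0.5 classifies as active (ties to positive); MCC with a zero
denominator is defined as 0. Hyper-parameter search is a seeded random
search over `n_estimators`, `max_depth`, and log-uniform `learning_rate`,
selecting the best mean cross-validated AUC on cluster-grouped folds —
grouping is kept in the inner loop for consistency with the leakage
principle (row-random folds remain available by flag).

SBFS removes, at each step, the feature whose removal maximizes pooled
cross-validated MCC, then conditionally re-includes any previously removed
feature that beats the best score yet seen at the resulting subset size
(the standard floating rule, which also prevents cycling). The chosen
subset is the argmax of MCC over the visited trace; ties prefer the smaller
subset, then the earlier visit — parsimony over optimism. Selection cost is
quadratic in the feature count times one CV per candidate, so the default
selection model is deliberately light (20 trees, depth 3, learning rate
0.5) and the fold count and stopping size (`min_features`) are exposed; the
test suite exercises recovery on 50 features at n = 2000 with 2-fold
grouped CV stopping at 35 features, which finishes in well under a minute
per run while leaving enough trace to distinguish signal from noise
features.

## Screening metrics

Ranking is score-descending with ligand-id tie-breaks — reproducibility
over optimism, since random tie-breaking lets lucky orderings inflate
enrichment. The top-n selection uses the ceiling (1 % of 1000 → 10, of
1034 → 11). EF_f = found / expected with expected = n_actives · n_sel / N;
EF is 0 when no active is selected and attains N/n_actives when the
selection is saturated. AUC is the Mann–Whitney probability with ties worth
one half. Method comparison removes near ties (|ΔEF1%| strictly below 3),
counts wins, and applies the exact binomial test at p = ½; the two-sided
p-value follows the minlike convention (sum of outcome probabilities not
exceeding the observed count's), with a one-sided alternative by flag. With
every target tied the p-value is undefined and flagged rather than
invented.

## Synthetic test bed

The fixture generators exist to exercise contracts, not biophysics:

* The toy complex is a spherical shell of free-standing alanines around an
  embedded small molecule — a "cage" (enclosure ≈ 1) or a "bowl"
  (hemisphere, open top). The shell radius adapts to the ligand so fixtures
  are clash-free, curation-passing, and featurizable with zero sentinels.
  Residues are not peptide-bonded; backbone amide hydrogens without a
  preceding residue are skipped by design and counted in the protonation
  report.
* Feature tables draw informative features from unit-variance normals
  whose class means differ by `effect_size` (in SD units); noise features
  are class-independent. Confound mode ties labels to cluster parity and
  plants a cluster-fingerprint feature, producing the leakage scenario:
  row-random CV looks strong, grouped CV collapses to chance.
* Benchmarks draw decoy scores from N(0,1) and active scores shifted by a
  per-method separation scaled by per-target lognormal jitter shared across
  methods, so per-target comparisons are paired.

Passing tests on this bed demonstrates the statistical machinery (metric
arithmetic, fold hygiene, selection behaviour, calibration under nulls) and
the geometric contracts (invariance, oracle agreement). It does not
demonstrate chemical accuracy on real complexes: real pockets flex, real
decoys are not guaranteed inactive, and real feature distributions are far
from Gaussian.

## Known limitations

* Protonation ignores tautomer equilibria and pKa shifts in the protein
  environment.
* No electrostatics or solvation terms; no protein flexibility; ligand
  strain uses a single fixed-seed conformer ensemble.
* The hydrophobic/apolar typing is distance-inferred rather than
  template-perfect for exotic residues.
* Greedy centroid clustering approximates but does not reproduce
  profile-based clustering tools; the adapter exists precisely so users can
  substitute one.
* EF at small fractions is a high-variance statistic on targets with few
  actives; the near-tie threshold of 3 EF1% units absorbs part of that
  noise but is itself a convention.
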
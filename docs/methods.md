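# Methods

`sfbench` is a workbench for comparing binding-affinity scoring functions —
models that map a protein–ligand complex structure to a predicted binding
affinity in pKd/pKi units (−log10 of the dissociation or inhibition constant
in molar). It implements two model families under one fixed training
protocol, three structural feature blocks, and three evaluation regimes, and
ships a synthetic-data module so the whole pipeline is testable without any
structural download.

## Structural model of a complex

A complex is reduced to two element-typed heavy-atom clouds. Hydrogens and
waters are always discarded. Protein atoms are restricted to the four
element types C, N, O, S; ligand atoms to the nine common heavy-atom types
C, N, O, S, P, F, Cl, Br, I. Atoms outside these sets (metal ions,
cofactor metals, boron, selenium …) are excluded from featurization and
counted in a log summary; this keeps the feature space dense and matches
the four-by-nine typing scheme throughout. Coordinates are used as read
(Å, no superposition or centering). The ligand's rotatable-bond count
`n_rot` — a flexibility/entropy proxy — is taken from the PDBQT `TORSDOF`
record or perceived by RDKit from Mol2 connectivity; it may be absent at
parse time but is required to build the Vina feature block.

## Feature blocks

**elem36** — occurrence counts of intermolecular contacts per
(protein element, ligand element) pair: entry (P, L) counts protein–ligand
atom pairs with Euclidean distance ≤ cutoff. 4 × 9 = 36 nonnegative integer
features, columns named `C.C … S.I` in protein-major order. The cutoff
defaults to 12 Å, the published value for this family of contact
descriptors; it is a configuration knob and is surfaced in logs. The
boundary uses ≤ (a pair at exactly the cutoff counts).

**vina** — six terms in the style of AutoDock Vina, functions of the
surface distance d = r − R_i − R_j (van der Waals radii per element,
bundled in `sfbench/data/vina_radii.csv`, overridable):

| term | form | typing restriction |
|---|---|---|
| Gauss1 | exp(−(d/0.5)²) | all pairs |
| Gauss2 | exp(−((d−3)/2)²) | all pairs |
| Repulsion | d² if d < 0 else 0 | all pairs |
| Hydrophobic | ramp 1→0 over d ∈ [0.5, 1.5] | hydrophobic-typed pairs |
| HBonding | ramp 1→0 over d ∈ [−0.7, 0] | donor/acceptor-capable pairs |
| Nrot | copies `n_rot` | — |

Pairs beyond 8 Å interatomic distance (default) contribute nothing. Because
a bare PDB protein carries no connectivity, atom typing is element-level:
every carbon counts as hydrophobic (on the ligand side also F/Cl/Br/I, as
in Vina's typing), and every N or O is donor/acceptor-capable. This is an
approximation to connectivity-aware typing and is the documented behaviour,
not a fallback.

**cyscore** — the four empirical energy terms of an external scoring
function (hydrophobic free energy, van der Waals, hydrogen bond, ligand
conformational entropy). Computing them requires that program's
curvature-dependent surface model, which is out of scope here by design;
they are consumed as precomputed columns joined by complex ID. No
substitution (e.g. deriving the entropy term from `n_rot`) is attempted.

Assembled tables follow the fixed column order cyscore, vina, elem36, so the
standard model kinds correspond to column subsets of sizes 4 (MLR/RF on the
energy terms), 10 (+Vina), 46 (+contacts).

## Models and training protocol

**MLR** — ordinary least squares with intercept:
ŷ = C + Σ_k k_f · f. A rank-deficient design raises an error naming the
collinear columns rather than silently pseudo-inverting, since the point of
the linear model is interpretable coefficients.

**Random forest** — an ensemble of 500 regression trees (default) grown on
bootstrap samples, prediction = arithmetic mean over trees. The single
tuned hyperparameter is mtry, the number of candidate features examined per
split: one forest is trained for every mtry from 1 to p, and the forest
with the lowest RMSE on out-of-bag (OOB) samples wins. Ties go to the
smallest mtry (cheaper, more decorrelated trees). The bootstrap is drawn
once from the user's seed and shared across the sweep, so the whole
protocol consumes exactly one seed; tree-level seeds are spawned
deterministically from it, making the fit bit-reproducible on a fixed
platform. Remaining tree hyperparameters follow classical regression-forest
defaults: minimum leaf size 5, unlimited depth. Samples that appear in
every bootstrap (possible at tiny n) are dropped from OOB aggregates with a
warning. The forest stores its per-tree bootstrap record, so OOB
predictions are exactly recomputable — the test suite does this as an
independent oracle, and an sklearn forest at matched settings serves as an
external accuracy cross-check.

**Permutation importance (%IncMSE)** — for each feature, its values are
shuffled among each tree's OOB samples (one permutation per feature per
tree), the tree predictions are re-aggregated into forest-level OOB
predictions, and the report gives 100 × (MSE_permuted − MSE_baseline) /
MSE_baseline. Negative values occur for noise features and are reported
as-is. An identity-permutation hook exists purely so tests can assert the
zero baseline exactly.

## Metrics

For measured y and predicted p over a test set of size N:

* RMSE = √(Σ(y−p)²/N) — absolute accuracy, pKd units.
* SD — residual standard error of the simple linear regression of y on p,
  denominator N−2 (an N−1 variant is available as a flag for comparisons
  with studies using that convention).
* Rp — Pearson correlation; Rs — Spearman with average-rank ties;
  optional Rk — Kendall tau-b.

SD, Rp, Rs are invariant under positive affine maps of the predictions
(so they compare ranking/correlation quality regardless of calibration);
RMSE is not, and is the metric to read when absolute affinities matter.
Constant vectors make the correlations undefined; they are reported as NaN
with a warning and excluded from harness averages (with a count), rather
than raising.

## Validation regimes

**Round-robin k-fold partition** — records are sorted by ascending
affinity (ties broken by complex ID) and dealt cyclically into k folds, so
each fold spans essentially the full affinity range and the split is fully
deterministic. At the 2959-complex benchmark scale with k = 5 this yields
fold sizes 592/592/592/592/591, and merging folds {1}, {1,3}, {1,3,4},
{1,3,4,5} produces the incremental training schedule 592/1184/1776/2367
evaluated against the 592-complex fold 2.

**Cross validation** — each fold tested once, model trained on the rest;
the summary row is the unweighted mean of per-fold metrics (not pooled
predictions — the two differ, and averaging matches how such tables are
conventionally printed).

**Leave-cluster-out cross validation (LCOCV)** — complexes belong to
protein families (in real data: 90% sequence-identity clusters, consumed
from file, never recomputed here). Families with ≥ 10 complexes become
individual clusters lettered A, B, … in order of descending size (a
convention; ≥ 24 such families is an error as the letter space A..W is
exhausted); families of 4–9 pool into cluster X, 2–3 into Y, singletons
into Z. Each cluster is held out in turn; summary rows are the unweighted
mean and sample standard deviation (ddof 1) over clusters. LCOCV probes
generalization to genuinely unseen target proteins and is expected to be
substantially more pessimistic than a random split — the pessimism is
itself asserted in the tests.

**Learning curves** — nested training sets, disjoint from a fixed test
set, each model refit per size. Train/test ID-set disjointness is asserted
inside every harness; leakage is an error, never a warning.

## Synthetic data

The generator emulates the statistical structure of a scoring-function
benchmark, not its physics. Toy complexes are uniform atom clouds in a
25 Å box with the ligand placed near the protein centroid (so contacts
exist at realistic cutoffs) and element frequencies loosely following real
compositions — sufficient for exercising geometric featurizers and their
invariances, nothing more. Benchmark datasets draw 4 energy-like
continuous columns and 16 count-like Poisson columns (20 features total)
and generate affinities as

y = C + Σ βᵢzᵢ + Σ w·zᵢzⱼ + family shift + ε,

on standardized features z, with C = 6 pKd, βᵢ = 0.8·0.85^i, six pairwise
interaction terms of weight 0.8 among the leading features, family shifts
N(0, 0.7²) across 10 families, and ε ~ N(0, 0.5²) — an error scale
plausible for heterogeneous experimental affinity data. These defaults put
simulated affinities in roughly the 2–12 pKd range observed in curated
sets. The interaction terms implement non-additivity — the reason a
flexible regressor can beat a fixed additive form; the family shifts
implement the clustered structure LCOCV needs and are used only by the
LCOCV fixture (in the affinity-stratified fixtures they would act as noise
the features cannot explain). Every generative parameter is recorded in a
manifest, enabling exact recovery tests: on noiseless interaction-free
data OLS reproduces the generative response to machine precision, and
permutation-importance rankings track the generative effect magnitudes.

What passing synthetic tests do *not* show: real structural data have
correlated features, pose noise, binding-site chemistry and family-feature
correlations that no independent-column generator reproduces. The
synthetic results validate the machinery and the direction of the
model-comparison effects, not the absolute performance levels reported on
real benchmark sets.

## Problem sizes and numerical choices

The headline learning-curve computation runs the full protocol (500 trees,
mtry swept 1..20, single seed) over the 592/1184/1776/2367 schedule at
p = 20 features — chosen so a complete run takes minutes on one core while
keeping the full sweep intact. Feature-table CSV round-trips preserve 12
significant digits. Seeds are consumed through `numpy.random.Generator` /
`SeedSequence` spawning only; no global RNG state is touched. Degenerate
inputs (empty ligands after filtering, constant prediction vectors,
all-in-bag samples) are handled by the documented warning/NaN/error
behaviour above rather than ad hoc.

## Known limitations

* PDB dialect coverage is deliberately shallow: first altloc conformer
  only, no insertion-code handling, no sanitization or protonation.
* Vina-term atom typing is element-level (see above); numbers will differ
  from connectivity-aware implementations, though the functional forms and
  invariances match.
* The cyscore energy block cannot be computed internally; workflows
  needing it must supply the columns.
* LCOCV cluster labels are consumed from file; sequence clustering is out
  of scope.
* Forest training is single-threaded by design (reproducibility over
  speed); a full 46-feature mtry sweep at several thousand samples is an
  overnight-scale computation, which is why the shipped benchmarks use 20
  features.
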
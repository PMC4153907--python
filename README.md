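# sfbench

A workbench for building and benchmarking protein–ligand binding-affinity
**scoring functions** — models that map a 3-D protein–ligand complex to a
predicted binding affinity in pKd/pKi units (−log10 molar). It is aimed at
structural bioinformatics / computational drug-discovery researchers who
want to compare a classical additive scoring model against a
machine-learning one under controlled, reproducible protocols.

The core comparison is between two regression philosophies on the same
features:

* **MLR** — the classical additive form ŷ = C + Σ k_f·f, fit by ordinary
  least squares; interpretable coefficients, fixed functional form.
* **Random forest** — 500 regression trees per forest, one forest per
  candidate mtry ∈ {1..p}, winner chosen by lowest out-of-bag RMSE, a
  single random seed for the whole sweep; no functional-form assumption,
  so non-additive structure in the data (interaction effects between
  features) is learnable.

Features come in three blocks: four external empirical energy terms
(consumed as precomputed columns), six AutoDock-Vina-style terms
(two Gaussian steric terms, repulsion, hydrophobic contact, hydrogen
bonding, rotatable-bond count), and 36 element-pair contact counts
(4 protein × 9 ligand heavy-atom types within a 12 Å cutoff). Evaluation
offers per-test-set metrics (RMSE, residual standard error SD, Pearson Rp,
Spearman Rs, optional Kendall Rk), a deterministic affinity-stratified
round-robin k-fold partitioner, leave-cluster-out cross validation over
protein families, incremental-training-size learning curves, and
permutation variable importance (%IncMSE). A synthetic-data module
generates element-typed atom clouds and affinity responses with controlled
additive, non-additive and noise components, so everything is testable
end-to-end with no structural download. See `docs/methods.md` for the full
model and protocol description.

## Worked example

`examples/05_learning_curve.py` builds a 1000-complex synthetic benchmark
with strong pairwise interactions, splits it round-robin, and evaluates
both models at three nested training sizes against a fixed test fold:

```
model  n_train  rmse    sd    rp    rs    n
  MLR      200 2.283 2.236 0.486 0.504 200
  MLR      400 2.246 2.228 0.492 0.516 200
  MLR      800 2.218 2.215 0.501 0.515 200
   RF      200 2.145 2.119 0.561 0.565 200
   RF      400 1.990 1.952 0.646 0.630 200
   RF      800 1.793 1.716 0.742 0.704 200
```

Read down each model's rows: the forest's Pearson correlation climbs from
0.561 to 0.742 as training data quadruples — it is still learning the
interaction structure — while the linear model is flat at ≈ 0.49–0.50
because its additive form is already saturated at the smallest size. RMSE
tells the same story in absolute pKd units. This is the qualitative
behaviour that makes flexible scoring functions worth their training-data
appetite, reproduced at desk scale.

The other examples each demonstrate one capability: featurizing a complex
(`01`), the mtry sweep and OOB selection (`02`), round-robin cross
validation (`03`), leave-cluster-out validation (`04`), and permutation
importance (`06`). A thin CLI mirrors the library
(`sfbench ingest|featurize|train|importance|crossval|lcocv|curve|synth`).

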
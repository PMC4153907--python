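"""Synthetic complexes and benchmark datasets.

Everything downstream (featurization, model fits, the three validation
harnesses) is exercised on data from this module, so no structural download
is required.  Two kinds of object are generated:

* toy element-typed 3-D atom clouds shaped like protein-ligand complexes
  (for the geometric featurizers), and
* feature/affinity datasets with controlled additive, non-additive
  (pairwise-interaction) and noise structure on the pKd scale, optionally
  with protein-family shifts for the leave-cluster-out regime.

Affinity model: with standardized features z_i,

    y = C + sum_i beta_i z_i + sum_(i,j) w_ij z_i z_j + family_shift + eps

with eps ~ N(0, noise_sd^2).  Defaults put the simulated affinities in the
empirical 2-12 pKd range.  Every generative parameter is recorded in a
manifest so recovery tests can check against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .complexio import (
    LIGAND_ELEMENTS,
    PROTEIN_ELEMENTS,
    AffinityRecord,
    AffinityTable,
    AtomRecord,
    ComplexStructure,
    FeatureTable,
    write_affinity_table,
)
from .evaluate import round_robin_partition

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "gen_toy_complex",
    "gen_dataset",
    "benchmark_fixture",
    "DEFAULT_INTERACTIONS",
]

#: Default pairwise interaction terms (i, j, weight) for the non-additive
#: regime: six pairs with weight comparable to the leading main effects.
DEFAULT_INTERACTIONS: tuple[tuple[int, int, float], ...] = (
    (0, 1, 0.8), (2, 3, 0.8), (0, 4, 0.8),
    (5, 6, 0.8), (1, 7, 0.8), (8, 9, 0.8),
)


@dataclass
class SyntheticSpec:
    """Generative recipe for a synthetic benchmark dataset.

    Features come in two flavours mirroring real scoring-function inputs:
    ``n_continuous`` energy-like columns (Gaussian, kcal/mol-like scale) and
    ``n_counts`` contact-count-like columns (Poisson).  The affinity model
    acts on standardized features so no block dominates by construction.
    """

    n_complexes: int = 200
    protein_atoms: tuple[int, int] = (40, 120)
    ligand_atoms: tuple[int, int] = (8, 30)
    box_size: float = 25.0  # Å
    n_continuous: int = 4
    n_counts: int = 16
    coefficients: Sequence[float] | None = None  # default 0.8 * 0.85**i
    intercept: float = 6.0  # pKd
    interactions: Sequence[tuple[int, int, float]] = ()
    noise_sd: float = 0.5  # pKd
    n_families: int = 10
    family_sd: float = 0.7  # pKd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        if self.noise_sd < 0 or self.family_sd < 0:
            raise ValueError("noise/family s.d. must be nonnegative")
        if self.box_size <= 0:
            raise ValueError("box size must be positive")
        p = self.n_continuous + self.n_counts
        for i, j, _ in self.interactions:
            if not (0 <= i < p and 0 <= j < p):
                raise ValueError(f"interaction ({i},{j}) references unknown feature")

    @property
    def n_features(self) -> int:
        return self.n_continuous + self.n_counts


@dataclass
class SyntheticDataset:
    """A generated benchmark: features, affinities, family labels, truth."""

    features: FeatureTable
    affinities: AffinityTable
    families: dict[str, str]
    manifest: dict = field(default_factory=dict)


def gen_toy_complex(
    complex_id: str = "syn1",
    n_protein: int = 60,
    n_ligand: int = 15,
    box_size: float = 25.0,
    seed: int = 0,
    n_rot_range: tuple[int, int] = (0, 12),
) -> ComplexStructure:
    """Generate one toy complex: protein atoms uniform in a cubic box,
    ligand atoms in a small ball near the protein centroid (so intermolecular
    contacts exist at realistic cutoffs), elements drawn from the role sets.
    """
    if box_size <= 0:
        raise ValueError("box size must be positive")
    rng = np.random.default_rng(seed)
    p_xyz = rng.uniform(0.0, box_size, size=(n_protein, 3))
    centroid = p_xyz.mean(axis=0) if n_protein else np.full(3, box_size / 2)
    # ligand within contact range of the protein centroid
    l_xyz = centroid + rng.normal(scale=box_size / 8, size=(n_ligand, 3))
    # protein is mostly carbon, as in real structures
    p_elems = rng.choice(PROTEIN_ELEMENTS, size=n_protein, p=[0.62, 0.17, 0.17, 0.04])
    l_probs = np.array([0.55, 0.12, 0.15, 0.03, 0.02, 0.05, 0.05, 0.02, 0.01])
    l_elems = rng.choice(LIGAND_ELEMENTS, size=n_ligand, p=l_probs)
    protein = [AtomRecord(e, xyz, "protein") for e, xyz in zip(p_elems, p_xyz)]
    ligand = [AtomRecord(e, xyz, "ligand") for e, xyz in zip(l_elems, l_xyz)]
    n_rot = int(rng.integers(n_rot_range[0], n_rot_range[1] + 1))
    return ComplexStructure(complex_id, protein, ligand, n_rot)


def _default_coefficients(p: int) -> np.ndarray:
    return 0.8 * 0.85 ** np.arange(p)


def gen_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a feature/affinity dataset under the spec's affinity model.

    Feature columns are named ``E1..`` (energy-like, tagged cyscore-style
    continuous) and ``K1..`` (count-like, tagged elem36-style); complex IDs
    are ``s0001`` etc.  The manifest records coefficients, interactions,
    family shifts, noise level and seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_complexes, spec.n_features

    cont = rng.normal(loc=-5.0, scale=2.0, size=(n, spec.n_continuous))
    lam = rng.uniform(5.0, 50.0, size=spec.n_counts)
    counts = rng.poisson(lam, size=(n, spec.n_counts)).astype(float)
    X = np.column_stack([cont, counts]) if spec.n_counts else cont

    # standardize for the response so neither block dominates by scale
    mu, sigma = X.mean(axis=0), X.std(axis=0)
    sigma[sigma == 0] = 1.0
    Z = (X - mu) / sigma

    beta = (np.asarray(spec.coefficients, dtype=float)
            if spec.coefficients is not None else _default_coefficients(p))
    if beta.shape != (p,):
        raise ValueError(f"coefficients must have length {p}")

    y = spec.intercept + Z @ beta
    for i, j, w in spec.interactions:
        y = y + w * Z[:, i] * Z[:, j]

    ids = [f"s{i + 1:04d}" for i in range(n)]
    fam_names = [f"fam{f + 1:02d}" for f in range(spec.n_families)]
    fam_idx = rng.integers(0, spec.n_families, size=n)
    shifts = rng.normal(0.0, spec.family_sd, size=spec.n_families)
    y = y + shifts[fam_idx]
    y = y + rng.normal(0.0, spec.noise_sd, size=n)

    names = ([f"E{i + 1}" for i in range(spec.n_continuous)]
             + [f"K{i + 1}" for i in range(spec.n_counts)])
    tags = {f"E{i + 1}": "external" for i in range(spec.n_continuous)}
    tags.update({f"K{i + 1}": "elem36" for i in range(spec.n_counts)})
    features = FeatureTable(pd.DataFrame(X, index=ids, columns=names), tags)
    records = [AffinityRecord(cid, float(v)) for cid, v in zip(ids, y)]
    families = {cid: fam_names[f] for cid, f in zip(ids, fam_idx)}

    manifest = {
        "spec": asdict(spec),
        "coefficients": beta.tolist(),
        "interactions": [list(t) for t in spec.interactions],
        "family_shifts": dict(zip(fam_names, shifts.tolist())),
        "feature_means": mu.tolist(),
        "feature_sds": sigma.tolist(),
    }
    return SyntheticDataset(features, AffinityTable(records, families=families),
                            families, manifest)


# ---------------------------------------------------------------------------
# ready-made harness fixtures
# ---------------------------------------------------------------------------

def _lcocv_spec(seed: int) -> SyntheticSpec:
    # family plan guarantees all of A.. (>=10), X (4-9), Y (2-3), Z (1)
    return SyntheticSpec(
        n_complexes=320, n_families=14, family_sd=0.7,
        interactions=DEFAULT_INTERACTIONS, seed=seed,
    )


def benchmark_fixture(kind: str, seed: int = 0, out_dir: str | Path | None = None):
    """Build the ready-made input bundle for one harness.

    ``kind`` is one of:

    * ``"crossval"`` -- 2959 complexes (the round-robin benchmark size) with
      non-additive affinity structure, plus the deterministic 5-fold
      partition.
    * ``"learning_curve"`` -- same dataset, plus the incremental nested
      training sets built from folds {1}, {1,3}, {1,3,4}, {1,3,4,5} and the
      fold-2 test set (sizes 592 / 1184 / 1776 / 2367 vs 592).
    * ``"lcocv"`` -- a clustered dataset whose family sizes produce
      individual clusters as well as the pooled X, Y and Z clusters.

    Returns a dict bundle; with ``out_dir`` the file set each harness (and
    the CLI) consumes is also written, along with a manifest of the
    generative truth.
    """
    if kind in ("crossval", "learning_curve"):
        # family structure is an LCOCV concern; the affinity-stratified
        # benchmarks use the plain non-additive regime (unlearnable family
        # shifts would only add noise the features cannot explain)
        spec = SyntheticSpec(
            n_complexes=2959, family_sd=0.0,
            interactions=DEFAULT_INTERACTIONS, seed=seed,
        )
        data = gen_dataset(spec)
        partition = round_robin_partition(data.affinities, k=5)
        bundle = {"kind": kind, "data": data, "partition": partition}
        if kind == "learning_curve":
            merges = ([1], [1, 3], [1, 3, 4], [1, 3, 4, 5])
            bundle["training_sets"] = [partition.merged_ids(m) for m in merges]
            bundle["test_set"] = partition.fold_ids(2)
    elif kind == "lcocv":
        spec = _lcocv_spec(seed)
        data = gen_dataset(spec)
        # reshape family sizes so every cluster category appears
        data = _force_cluster_plan(data, seed)
        bundle = {"kind": kind, "data": data, "families": data.families}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _force_cluster_plan(data: SyntheticDataset, seed: int) -> SyntheticDataset:
    """Relabel families so the size categories >=10, 4-9, 2-3 and 1 all
    occur: a deterministic size plan is dealt over the complexes."""
    # pooled clusters must each hold >= 3 complexes so test metrics exist
    plan = [80, 60, 40, 25, 18, 12, 10, 9, 7, 5, 4, 3, 3, 2, 1, 1, 1]
    n = len(data.affinities.records)
    plan = _fit_plan(plan, n)
    ids = data.affinities.complex_ids
    families: dict[str, str] = {}
    pos = 0
    for f, size in enumerate(plan):
        for cid in ids[pos:pos + size]:
            families[cid] = f"fam{f + 1:02d}"
        pos += size
    # re-apply family shifts under the new labels
    rng = np.random.default_rng(seed + 1)
    shifts = {f"fam{f + 1:02d}": rng.normal(0.0, 0.7) for f in range(len(plan))}
    records = [
        AffinityRecord(r.complex_id, r.affinity + shifts[families[r.complex_id]])
        for r in data.affinities.records
    ]
    manifest = dict(data.manifest, family_plan=plan,
                    family_shifts_extra=shifts)
    return SyntheticDataset(data.features,
                            AffinityTable(records, families=families),
                            families, manifest)


def _fit_plan(plan: list[int], n: int) -> list[int]:
    total = sum(plan)
    if total > n:
        raise ValueError(f"cluster plan needs {total} complexes, have {n}")
    plan = list(plan)
    plan[0] += n - total  # absorb the remainder into the largest family
    return plan


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    import json

    out_dir.mkdir(parents=True, exist_ok=True)
    data: SyntheticDataset = bundle["data"]
    data.features.to_csv(out_dir / "features.csv")
    partition = bundle.get("partition")
    write_affinity_table(
        out_dir / "affinities.csv",
        data.affinities.records,
        partition=partition.assignment if partition is not None else None,
        families=data.families if bundle["kind"] == "lcocv" else None,
    )
    if "training_sets" in bundle:
        schedule = {
            "test_set": bundle["test_set"],
            "training_sets": bundle["training_sets"],
        }
        (out_dir / "schedule.json").write_text(json.dumps(schedule))
    (out_dir / "manifest.json").write_text(json.dumps(data.manifest, default=str))
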
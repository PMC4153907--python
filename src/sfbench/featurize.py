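"""Structural featurization of protein-ligand complexes.

Three feature blocks are supported:

* ``cyscore`` -- the four empirical energy terms (hydrophobic, van der Waals,
  hydrogen bond, ligand conformational entropy).  These come from an external
  surface-area-based program and are consumed as precomputed columns, never
  computed here.
* ``vina`` -- the six AutoDock-Vina-style terms: two Gaussian steric
  attraction terms, steric repulsion, hydrophobic contact, hydrogen bonding,
  and the ligand rotatable-bond count N_rot.
* ``elem36`` -- occurrence counts of intermolecular heavy-atom contacts for
  the 4 protein x 9 ligand element-type pairs, within a distance cutoff.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .complexio import (
    LIGAND_ELEMENTS,
    PROTEIN_ELEMENTS,
    AffinityTable,
    ComplexStructure,
    FeatureTable,
)

logger = logging.getLogger("sfbench.featurize")

#: Column names of the 36 element-pair contact counts, protein-major order:
#: C.C, C.N, ..., C.I, N.C, ..., S.I.
ELEM36_NAMES: tuple[str, ...] = tuple(
    f"{p}.{l}" for p in PROTEIN_ELEMENTS for l in LIGAND_ELEMENTS
)

#: Column names of the six Vina-style terms.
VINA_NAMES: tuple[str, ...] = (
    "Gauss1", "Gauss2", "Repulsion", "Hydrophobic", "HBonding", "Nrot",
)

#: Canonical names of the four external energy terms.
CYSCORE_NAMES: tuple[str, ...] = ("Hydrophobic_E", "Vdw", "HBond", "Ent")

# Element-level Vina atom typing.  Without connectivity (bare PDB proteins)
# carbons cannot be checked for bonded N/O, so all carbons count as
# hydrophobic; halogens on the ligand side are hydrophobic as in Vina's
# atom-typing scheme.  N and O are treated as both donor- and
# acceptor-capable.
_HYDROPHOBIC_PROTEIN = {"C"}
_HYDROPHOBIC_LIGAND = {"C", "F", "Cl", "Br", "I"}
_HBOND_CAPABLE = {"N", "O"}

_DEFAULT_CONTACT_CUTOFF = 12.0  # Å, elem36 contact cutoff
_DEFAULT_VINA_CUTOFF = 8.0  # Å, interatomic distance cutoff for Vina terms


def load_vdw_radii(path: str | Path | None = None) -> dict[str, float]:
    """Load the van der Waals radius table (Å); bundled defaults unless a
    CSV with columns element,radius is supplied."""
    if path is None:
        source = resources.files("sfbench.data").joinpath("vina_radii.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    radii: dict[str, float] = {}
    for row in csv.DictReader(text.splitlines()):
        radii[row["element"]] = float(row["radius"])
    return radii


@dataclass
class FeatureSetSpec:
    """Which feature blocks to compute and with what geometric parameters."""

    blocks: tuple[str, ...] = ("cyscore", "vina", "elem36")
    external_sources: list = field(default_factory=list)  # paths or FeatureTables
    contact_cutoff: float = _DEFAULT_CONTACT_CUTOFF
    vina_cutoff: float = _DEFAULT_VINA_CUTOFF

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("blocks must be non-empty")
        unknown = [b for b in self.blocks if b not in ("cyscore", "vina", "elem36")]
        if unknown:
            raise ValueError(f"unknown feature blocks: {unknown}")
        if self.contact_cutoff <= 0 or self.vina_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


def elem_pair_features(
    complex_: ComplexStructure, cutoff: float = _DEFAULT_CONTACT_CUTOFF
) -> np.ndarray:
    """Count protein-ligand heavy-atom pairs within ``cutoff`` Å, per
    (protein element, ligand element) pair.

    Returns a length-36 integer vector indexed protein-major as in
    :data:`ELEM36_NAMES`; a pair at exactly the cutoff distance counts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    counts = np.zeros(len(ELEM36_NAMES), dtype=np.int64)
    p_xyz = complex_.coords("protein")
    l_xyz = complex_.coords("ligand")
    if len(p_xyz) == 0 or len(l_xyz) == 0:
        return counts
    p_idx = np.array([PROTEIN_ELEMENTS.index(e) for e in complex_.elements("protein")])
    l_idx = np.array([LIGAND_ELEMENTS.index(e) for e in complex_.elements("ligand")])
    within = cdist(p_xyz, l_xyz) <= cutoff
    pair_codes = p_idx[:, None] * len(LIGAND_ELEMENTS) + l_idx[None, :]
    np.add.at(counts, pair_codes[within], 1)
    return counts


def _surface_distances(
    complex_: ComplexStructure, cutoff: float, radii: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise surface distances d = r - R_i - R_j for protein-ligand pairs
    with interatomic distance r <= cutoff; returns (d, protein elements,
    ligand elements) for the retained pairs."""
    p_xyz = complex_.coords("protein")
    l_xyz = complex_.coords("ligand")
    if len(p_xyz) == 0 or len(l_xyz) == 0:
        return np.empty(0), np.empty(0, dtype=object), np.empty(0, dtype=object)
    r = cdist(p_xyz, l_xyz)
    keep = r <= cutoff
    p_elems = np.array(complex_.elements("protein"), dtype=object)
    l_elems = np.array(complex_.elements("ligand"), dtype=object)
    rp = np.array([radii[e] for e in p_elems])
    rl = np.array([radii[e] for e in l_elems])
    d = r - rp[:, None] - rl[None, :]
    ii, jj = np.nonzero(keep)
    return d[keep], p_elems[ii], l_elems[jj]


def vina_features(
    complex_: ComplexStructure,
    cutoff: float = _DEFAULT_VINA_CUTOFF,
    radii: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Compute the six Vina-style terms for one complex.

    The five geometric terms are sums over protein-ligand heavy-atom pairs
    within ``cutoff`` Å of pairwise functions of the surface distance
    d = r - R_i - R_j:

    * Gauss1 = exp(-(d/0.5)^2)
    * Gauss2 = exp(-((d-3)/2)^2)
    * Repulsion = d^2 for d < 0, else 0
    * Hydrophobic = ramp from 1 to 0 over d in [0.5, 1.5] Å, for pairs where
      both atoms are hydrophobic-typed
    * HBonding = ramp from 1 to 0 over d in [-0.7, 0] Å, for donor/acceptor-
      capable pairs (N or O on both sides)

    The sixth component copies the ligand rotatable-bond count.
    """
    if complex_.n_rot is None:
        raise ValueError(
            f"{complex_.complex_id}: n_rot is required for Vina features; supply "
            "a ligand format carrying torsion information or set n_rot explicitly"
        )
    radii = load_vdw_radii() if radii is None else dict(radii)
    d, pe, le = _surface_distances(complex_, cutoff, radii)

    gauss1 = float(np.exp(-((d / 0.5) ** 2)).sum())
    gauss2 = float(np.exp(-(((d - 3.0) / 2.0) ** 2)).sum())
    repulsion = float((np.minimum(d, 0.0) ** 2).sum())

    phobic_pair = np.array(
        [p in _HYDROPHOBIC_PROTEIN and l in _HYDROPHOBIC_LIGAND for p, l in zip(pe, le)],
        dtype=bool,
    )
    hydrophobic = float(np.clip((1.5 - d[phobic_pair]) / 1.0, 0.0, 1.0).sum())

    hb_pair = np.array(
        [p in _HBOND_CAPABLE and l in _HBOND_CAPABLE for p, l in zip(pe, le)],
        dtype=bool,
    )
    hbonding = float(np.clip(d[hb_pair] / -0.7, 0.0, 1.0).sum())

    return np.array([gauss1, gauss2, repulsion, hydrophobic, hbonding,
                     float(complex_.n_rot)])


def assemble_features(
    complexes: Sequence[ComplexStructure],
    spec: FeatureSetSpec,
    affinities: AffinityTable | None = None,
) -> FeatureTable:
    """Assemble a model-ready feature table from the requested blocks.

    Column order is fixed: cyscore block, then vina, then elem36.  The
    cyscore block is resolved from ``spec.external_sources``; any complex
    missing a required external row is an error listing the IDs.  When an
    affinity table is given, rows are aligned to (and restricted to) its
    record order.
    """
    if not complexes:
        raise ValueError("empty complex list")
    by_id = {c.complex_id: c for c in complexes}
    if len(by_id) != len(complexes):
        raise ValueError("duplicate complex ids in input")
    if affinities is not None:
        missing = [cid for cid in affinities.complex_ids if cid not in by_id]
        if missing:
            raise ValueError(f"complexes missing for affinity records: {missing}")
        order = affinities.complex_ids
    else:
        order = [c.complex_id for c in complexes]

    parts: list[FeatureTable] = []
    for block in ("cyscore", "vina", "elem36"):
        if block not in spec.blocks:
            continue
        if block == "cyscore":
            parts.append(_resolve_external(order, spec.external_sources))
        elif block == "vina":
            rows = np.stack([vina_features(by_id[cid], spec.vina_cutoff) for cid in order])
            df = pd.DataFrame(rows, index=order, columns=list(VINA_NAMES))
            parts.append(FeatureTable(df, {n: "vina" for n in VINA_NAMES}))
        else:
            rows = np.stack(
                [elem_pair_features(by_id[cid], spec.contact_cutoff) for cid in order]
            )
            df = pd.DataFrame(rows, index=order, columns=list(ELEM36_NAMES))
            parts.append(FeatureTable(df, {n: "elem36" for n in ELEM36_NAMES}))

    table = parts[0]
    for part in parts[1:]:
        table = table.merge(part)
    logger.info(
        "assembled %d x %d feature table (blocks: %s; contact cutoff %.1f Å)",
        len(table), len(table.feature_names), ",".join(spec.blocks), spec.contact_cutoff,
    )
    return table


def _resolve_external(order: Sequence[str], sources: Iterable) -> FeatureTable:
    tables = []
    for src in sources:
        if isinstance(src, FeatureTable):
            tables.append(src)
        else:
            tables.append(FeatureTable.from_csv(src, default_tag="cyscore"))
    if not tables:
        raise ValueError(
            "cyscore block requested but no external feature source provided"
        )
    merged = tables[0]
    for t in tables[1:]:
        merged = merged.merge(t)
    missing = [cid for cid in order if cid not in merged.complex_ids]
    if missing:
        raise ValueError(f"external feature source missing complex ids: {missing}")
    return merged.subset_rows(order)
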
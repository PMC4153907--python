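"""Domain types and file I/O for protein-ligand scoring-function benchmarks.

Structures are reduced to the element-typed heavy-atom clouds the contact
featurizer consumes: four protein element types (C, N, O, S) and nine ligand
element types (C, N, O, S, P, F, Cl, Br, I).  Affinities are pKd/pKi values
(-log10 molar).  Feature tables carry named per-complex feature vectors
organised in blocks (cyscore | vina | elem36 | external).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sfbench.complexio")

#: Protein heavy-atom element types retained for featurization.
PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")
#: Ligand heavy-atom element types retained for featurization.
LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")

#: Valid feature-block tags.
BLOCK_TAGS: tuple[str, ...] = ("cyscore", "vina", "elem36", "external")

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed; names the offending location."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element symbol, Cartesian position (Å), and role."""

    element: str
    position: np.ndarray  # shape (3,), Å
    role: str  # "protein" | "ligand"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"role must be 'protein' or 'ligand', got {self.role!r}")


@dataclass
class ComplexStructure:
    """A protein-ligand complex reduced to role-typed heavy atoms.

    ``n_rot`` is the ligand rotatable-bond count (flexibility proxy); it may be
    absent at parse time but is required when Vina-style features are computed.
    """

    complex_id: str
    protein_atoms: list[AtomRecord] = field(default_factory=list)
    ligand_atoms: list[AtomRecord] = field(default_factory=list)
    n_rot: int | None = None

    def __post_init__(self) -> None:
        if self.n_rot is not None and self.n_rot < 0:
            raise ValueError("n_rot must be nonnegative when present")

    def coords(self, role: str) -> np.ndarray:
        atoms = self.protein_atoms if role == "protein" else self.ligand_atoms
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in atoms])

    def elements(self, role: str) -> list[str]:
        atoms = self.protein_atoms if role == "protein" else self.ligand_atoms
        return [a.element for a in atoms]


@dataclass(frozen=True)
class AffinityRecord:
    """Measured binding affinity of one complex, in pKd/pKi units."""

    complex_id: str
    affinity: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.affinity):
            raise ValueError(f"affinity must be finite for {self.complex_id!r}")
        if not 0.0 <= self.affinity <= 15.0:
            warnings.warn(
                f"affinity {self.affinity} for {self.complex_id!r} is outside the "
                "plausible pKd range [0, 15]",
                stacklevel=2,
            )


@dataclass
class AffinityTable:
    """Affinity records in file order, plus optional partition / family columns."""

    records: list[AffinityRecord]
    partition: dict[str, int] | None = None  # complex_id -> fold index
    families: dict[str, str] | None = None  # complex_id -> protein-family label

    @property
    def complex_ids(self) -> list[str]:
        return [r.complex_id for r in self.records]

    @property
    def affinities(self) -> np.ndarray:
        return np.array([r.affinity for r in self.records])


class FeatureTable:
    """Per-complex named feature vectors assembled from tagged blocks.

    Thin wrapper around a pandas DataFrame (rows = complexes, columns =
    features) that additionally tracks, for every column, which block it
    belongs to: cyscore, vina, elem36 or external.
    """

    def __init__(self, data: pd.DataFrame, block_tags: Mapping[str, str]):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate complex ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature names: {dups}")
        missing = [c for c in data.columns if c not in block_tags]
        if missing:
            raise ValueError(f"columns without a block tag: {missing}")
        bad = {c: t for c, t in block_tags.items() if t not in BLOCK_TAGS}
        if bad:
            raise ValueError(f"unknown block tags: {bad}")
        self._df = data.astype(float)
        self._tags = {c: block_tags[c] for c in data.columns}

    # -- basic views ------------------------------------------------------

    @property
    def complex_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def block_tags(self) -> dict[str, str]:
        return dict(self._tags)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self._tags == other._tags
            and self._df.index.equals(other._df.index)
            and self._df.columns.equals(other._df.columns)
            and np.allclose(self._df.to_numpy(), other._df.to_numpy(), rtol=1e-11, atol=0)
        )

    # -- manipulation -----------------------------------------------------

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        unknown = [n for n in names if n not in self._df.columns]
        if unknown:
            raise KeyError(f"unknown feature columns: {unknown}")
        return FeatureTable(self._df[list(names)], {n: self._tags[n] for n in names})

    def subset_rows(self, ids: Sequence[str]) -> "FeatureTable":
        missing = [i for i in ids if i not in self._df.index]
        if missing:
            raise KeyError(f"unknown complex ids: {missing}")
        return FeatureTable(self._df.loc[list(ids)], self._tags)

    def block_columns(self, tag: str) -> list[str]:
        return [c for c in self._df.columns if self._tags[c] == tag]

    def merge(self, other: "FeatureTable") -> "FeatureTable":
        """Column-wise merge on complex_id; every id of self must be in other."""
        missing = [i for i in self._df.index if i not in other._df.index]
        if missing:
            raise ValueError(f"merge source missing complex ids: {missing}")
        clash = set(self._df.columns) & set(other._df.columns)
        if clash:
            raise ValueError(f"duplicate feature names in merge: {sorted(clash)}")
        joined = pd.concat([self._df, other._df.loc[self._df.index]], axis=1)
        return FeatureTable(joined, {**self._tags, **other._tags})

    # -- CSV round trip ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with a leading ``# blocks:`` metadata comment line."""
        path = Path(path)
        tagline = "# blocks: " + ";".join(f"{c}={t}" for c, t in self._tags.items())
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(tagline + "\n")
            self._df.to_csv(fh, index_label="complex_id", float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, default_tag: str = "external") -> "FeatureTable":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            tags: dict[str, str] = {}
            if first.startswith("# blocks:"):
                for item in first[len("# blocks:"):].strip().split(";"):
                    if item:
                        name, _, tag = item.partition("=")
                        tags[name] = tag
                body_start = fh.tell()
            else:
                body_start = 0
            fh.seek(body_start)
            try:
                df = pd.read_csv(fh, index_col=0)
            except pd.errors.ParserError as exc:
                raise FormatError(f"{path}: {exc}") from exc
        df.index = df.index.astype(str).str.lower()
        full_tags = {c: tags.get(c, default_tag) for c in df.columns}
        return cls(df, full_tags)


# ---------------------------------------------------------------------------
# structure readers
# ---------------------------------------------------------------------------

_NAME_ELEMENT_HINTS = {
    "CL": "Cl", "BR": "Br", "FE": "Fe", "ZN": "Zn", "MG": "Mg",
    "MN": "Mn", "NA": "Na", "CA": "Ca", "SE": "Se",
}


def _element_from_atom_name(name: str) -> str:
    """Heuristic element inference from a PDB atom name (used when the
    element column is blank).  Two-letter symbols are only trusted when the
    name starts in column 13 (metal / halogen convention)."""
    stripped = name.strip()
    two = stripped[:2].upper()
    if len(name) >= 2 and name[0] != " " and two in _NAME_ELEMENT_HINTS:
        return _NAME_ELEMENT_HINTS[two]
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _normalize_element(sym: str) -> str:
    sym = sym.strip()
    if not sym:
        raise ValueError("empty element symbol")
    return sym[0].upper() + sym[1:].lower()


def _read_protein_pdb(path: Path) -> list[AtomRecord]:
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("protein", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"{path}: unparsable PDB file ({exc})") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise FormatError(f"{path}: PDB file contains no model")

    atoms: list[AtomRecord] = []
    excluded: dict[str, int] = {}
    for residue in model.get_residues():
        if residue.get_resname().strip() in _WATER_RESNAMES:
            continue
        for atom in residue.get_atoms():
            # keep only the first altloc conformer
            if atom.get_altloc() not in (" ", "", "A"):
                continue
            elem = atom.element.strip() if atom.element else ""
            if not elem:
                elem = _element_from_atom_name(atom.get_fullname())
            elem = _normalize_element(elem)
            if elem in ("H", "D"):
                continue
            if elem not in PROTEIN_ELEMENTS:
                excluded[elem] = excluded.get(elem, 0) + 1
                continue
            atoms.append(AtomRecord(elem, np.asarray(atom.coord, dtype=float), "protein"))
    if excluded:
        logger.info(
            "%s: excluded %d protein atoms outside the C/N/O/S scheme: %s",
            path.name, sum(excluded.values()), dict(sorted(excluded.items())),
        )
    return atoms


# AutoDock atom type -> element (heavy atoms only; HD/H dropped)
_AD_TYPE_ELEMENT = {
    "C": "C", "A": "C", "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O", "S": "S", "SA": "S",
    "P": "P", "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
    "H": "H", "HD": "H", "HS": "H",
}


def _read_ligand_pdbqt(path: Path) -> tuple[list[AtomRecord], int | None, dict[str, int]]:
    atoms: list[AtomRecord] = []
    excluded: dict[str, int] = {}
    n_rot: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if line.startswith("TORSDOF"):
                try:
                    n_rot = int(line.split()[1])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad TORSDOF record") from exc
            elif rec in ("ATOM", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: bad coordinate fields in {line.rstrip()!r}"
                    ) from exc
                # the AutoDock atom type is the last field of the record
                ad_type = line.split()[-1]
                elem = _AD_TYPE_ELEMENT.get(ad_type.upper())
                if elem is None:
                    elem = _normalize_element(ad_type)
                if elem == "H":
                    continue
                if elem not in LIGAND_ELEMENTS:
                    excluded[elem] = excluded.get(elem, 0) + 1
                    continue
                atoms.append(AtomRecord(elem, np.array([x, y, z]), "ligand"))
    return atoms, n_rot, excluded


def _read_ligand_mol2(path: Path) -> tuple[list[AtomRecord], int | None, dict[str, int]]:
    try:
        from rdkit import Chem
        from rdkit.Chem import rdMolDescriptors
    except ImportError as exc:  # pragma: no cover - rdkit present in supported envs
        raise ImportError("Mol2 reading requires rdkit (install sfbench[chem])") from exc

    mol = Chem.MolFromMol2File(str(path), sanitize=True, removeHs=True)
    n_rot: int | None = None
    if mol is not None:
        n_rot = int(rdMolDescriptors.CalcNumRotatableBonds(mol))
    else:
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
        if mol is None:
            raise FormatError(f"{path}: RDKit could not parse Mol2 file")
        logger.info("%s: sanitization failed; n_rot unavailable", path.name)

    conf = mol.GetConformer()
    atoms: list[AtomRecord] = []
    excluded: dict[str, int] = {}
    for atom in mol.GetAtoms():
        elem = atom.GetSymbol()
        if elem in ("H", "D"):
            continue
        pos = conf.GetAtomPosition(atom.GetIdx())
        if elem not in LIGAND_ELEMENTS:
            excluded[elem] = excluded.get(elem, 0) + 1
            continue
        atoms.append(AtomRecord(elem, np.array([pos.x, pos.y, pos.z]), "ligand"))
    return atoms, n_rot, excluded


def read_complex(protein_path: str | Path, ligand_path: str | Path) -> ComplexStructure:
    """Read a protein (PDB) + ligand (Mol2 or PDBQT) pair into a ComplexStructure.

    Hydrogens and waters are dropped; heavy atoms outside the role element
    sets (protein: C/N/O/S; ligand: the nine common types) are excluded from
    the structure and reported through the ``sfbench.complexio`` logger.
    ``n_rot`` is populated from the PDBQT TORSDOF record or RDKit bond
    perception when available, else left absent.
    """
    protein_path = Path(protein_path)
    ligand_path = Path(ligand_path)
    protein_atoms = _read_protein_pdb(protein_path)

    suffix = ligand_path.suffix.lower()
    if suffix == ".pdbqt":
        ligand_atoms, n_rot, excluded = _read_ligand_pdbqt(ligand_path)
    elif suffix == ".mol2":
        ligand_atoms, n_rot, excluded = _read_ligand_mol2(ligand_path)
    else:
        raise FormatError(f"{ligand_path}: unsupported ligand format {suffix!r} "
                          "(expected .mol2 or .pdbqt)")
    if excluded:
        logger.info(
            "%s: excluded %d ligand atoms outside the nine-type scheme: %s",
            ligand_path.name, sum(excluded.values()), dict(sorted(excluded.items())),
        )
    if not ligand_atoms and not excluded:
        raise FormatError(f"{ligand_path}: ligand contains no heavy atoms")

    complex_id = protein_path.stem.lower()
    return ComplexStructure(complex_id, protein_atoms, ligand_atoms, n_rot)


# ---------------------------------------------------------------------------
# affinity tables
# ---------------------------------------------------------------------------

_ID_COLUMN_NAMES = ("complex_id", "pdb", "pdb_id", "id")
_AFFINITY_COLUMN_NAMES = ("affinity", "pkd", "pki", "pbindaff")


def read_affinity_table(path: str | Path) -> AffinityTable:
    """Read a CSV of complex IDs and measured affinities (pKd/pKi).

    Recognised optional columns: ``partition`` (integer fold labels) and
    ``family`` / ``cluster`` (protein-family labels for leave-cluster-out
    validation).  Complex IDs are lower-cased; duplicates are an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    cols = {c.lower(): c for c in df.columns}
    id_col = next((cols[n] for n in _ID_COLUMN_NAMES if n in cols), df.columns[0])
    aff_col = next((cols[n] for n in _AFFINITY_COLUMN_NAMES if n in cols), None)
    if aff_col is None:
        remaining = [c for c in df.columns if c != id_col]
        if not remaining:
            raise FormatError(f"{path}: no affinity column found")
        aff_col = remaining[0]

    ids = df[id_col].astype(str).str.lower()
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated complex ids: {dups}")

    records: list[AffinityRecord] = []
    for row_number, (cid, raw) in enumerate(zip(ids, df[aff_col]), start=2):
        try:
            aff = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: row {row_number}: non-numeric affinity {raw!r}"
            ) from exc
        if not np.isfinite(aff):
            raise FormatError(f"{path}: row {row_number}: non-finite affinity")
        records.append(AffinityRecord(cid, aff))

    partition = None
    if "partition" in cols:
        partition = {cid: int(v) for cid, v in zip(ids, df[cols["partition"]])}
    families = None
    fam_col = cols.get("family", cols.get("cluster"))
    if fam_col is not None:
        families = {cid: str(v) for cid, v in zip(ids, df[fam_col])}
    return AffinityTable(records, partition=partition, families=families)


def write_affinity_table(
    path: str | Path,
    records: Iterable[AffinityRecord],
    partition: Mapping[str, int] | None = None,
    families: Mapping[str, str] | None = None,
) -> None:
    """Write an affinity CSV in the shape of the benchmark's partition files."""
    records = list(records)
    data: dict[str, list] = {
        "complex_id": [r.complex_id for r in records],
        "affinity": [r.affinity for r in records],
    }
    if partition is not None:
        data["partition"] = [partition[r.complex_id] for r in records]
    if families is not None:
        data["family"] = [families[r.complex_id] for r in records]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
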
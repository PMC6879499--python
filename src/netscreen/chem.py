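"""Compound parsing and pairwise structural similarity.

Two similarity measures are provided:

* **MCS overlap coefficient** — the heavy-atom size ``n`` of the (connected)
  maximum common substructure of two molecules, normalised by the size of the
  smaller molecule: ``n / min(c1, c2)``.  The coefficient is 1.0 whenever the
  smaller molecule is wholly contained in the larger one, which makes it far
  more sensitive to local/fragment similarity between molecules of very
  different sizes than Tanimoto-style measures.
* **Morgan (ECFP) Tanimoto** — Tanimoto similarity of hashed circular
  fingerprints.

Hydrogens are excluded throughout: ``n``, ``c1`` and ``c2`` count heavy atoms
only, following standard cheminformatics convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, rdFMCS
from rdkit import DataStructs

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "CompoundSet",
    "McsParams",
    "McsResult",
    "SimilarityMatrix",
    "load_compounds",
    "mcs_overlap",
    "morgan_tanimoto",
    "similarity_matrix",
    "tanimoto_sets",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One parsed small molecule.

    ``mol`` is an RDKit molecule with sanitised (re-aromatised) perception,
    hydrogens implicit.  ``compound_id`` must be unique within a set.
    """

    compound_id: str
    name: str
    mol: Chem.Mol
    source_format: str  # sdf | mol | smiles

    def __post_init__(self) -> None:
        if self.mol is None or self.mol.GetNumHeavyAtoms() < 1:
            raise ValueError(
                f"compound {self.compound_id!r}: structure must have >= 1 heavy atom"
            )
        # parse must round-trip to a canonical line notation
        smi = Chem.MolToSmiles(self.mol)
        if not smi:
            raise ValueError(f"compound {self.compound_id!r}: cannot canonicalise")

    @property
    def n_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass
class CompoundSet:
    """Ordered collection of compounds; order defines matrix row order."""

    records: list[CompoundRecord]

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate compound ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: int | str) -> CompoundRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.compound_id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]


@dataclass(frozen=True)
class McsParams:
    """Matching rules for the maximum-common-substructure search.

    ``atom_compare`` is ``elements`` (atoms must share the element, the
    strict default) or ``any``; ``bond_compare`` is ``exact`` (bond orders
    must match exactly, aromatic only matches aromatic — the strict default),
    ``order`` (aromatic bonds also match the corresponding single/double
    Kekule orders) or ``any``.  Relaxing these emulates mismatch-tolerant
    "flexible" MCS searches.  ``timeout_s`` caps each pairwise search; on
    timeout the best substructure found so far is used and flagged, never
    silently.
    """

    timeout_s: float = 10.0
    ring_matches_ring: bool = False
    atom_compare: str = "elements"
    bond_compare: str = "exact"

    _ATOM = {"elements": rdFMCS.AtomCompare.CompareElements,
             "any": rdFMCS.AtomCompare.CompareAny}
    _BOND = {"exact": rdFMCS.BondCompare.CompareOrderExact,
             "order": rdFMCS.BondCompare.CompareOrder,
             "any": rdFMCS.BondCompare.CompareAny}

    def __post_init__(self) -> None:
        if self.atom_compare not in self._ATOM:
            raise ValueError(f"atom_compare must be one of {sorted(self._ATOM)}")
        if self.bond_compare not in self._BOND:
            raise ValueError(f"bond_compare must be one of {sorted(self._BOND)}")

    def _find_mcs(self, mols: Sequence[Chem.Mol]) -> rdFMCS.MCSResult:
        return rdFMCS.FindMCS(
            list(mols),
            atomCompare=self._ATOM[self.atom_compare],
            bondCompare=self._BOND[self.bond_compare],
            ringMatchesRingOnly=self.ring_matches_ring,
            timeout=max(1, int(round(self.timeout_s))),
        )


@dataclass(frozen=True)
class McsResult:
    """Size of the maximum common substructure and the overlap coefficient.

    ``coefficient == n / min(c1, c2)`` exactly; ``n == 0`` (coefficient 0.0)
    only when the two molecules share no atom type at all under the matching
    rules.  ``timed_out`` marks a coefficient computed from the best
    substructure found before the search timeout.
    """

    n: int
    c1: int
    c2: int
    coefficient: float
    timed_out: bool = False


def _parse_smiles_lines(lines: Iterable[str], strict: bool) -> list[tuple[str, Chem.Mol]]:
    out: list[tuple[str, Chem.Mol]] = []
    idx = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        idx += 1
        parts = line.split(None, 1)
        smiles = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"cpd_{idx}"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            msg = f"line {lineno}: unparseable SMILES {smiles!r}"
            if strict:
                raise ValueError(msg)
            logger.warning("skipping %s", msg)
            continue
        out.append((cid, mol))
    return out


def load_compounds(
    path: str | Path, format: str = "auto", strict: bool = False
) -> CompoundSet:
    """Read an SDF, MOL or SMILES file into a :class:`CompoundSet`.

    SMILES line format is ``SMILES[\\t ]id`` with ``#`` comments; ids default
    to the SDF title field or, when absent, to ``cpd_<index>`` (1-based file
    order).  Unparseable entries are skipped with a warning (``strict=True``
    raises instead).  SDF input is re-sanitised so kekulised structures get
    consistent aromaticity perception.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such compound file: {path}")
    if format == "auto":
        ext = path.suffix.lower().lstrip(".")
        format = {"sdf": "sdf", "mol": "mol", "smi": "smiles", "smiles": "smiles",
                  "txt": "smiles", "ism": "smiles"}.get(ext, "smiles")
    if format not in {"sdf", "mol", "smiles"}:
        raise ValueError(f"unknown format {format!r}")

    parsed: list[tuple[str, Chem.Mol]] = []
    if format == "smiles":
        parsed = _parse_smiles_lines(path.read_text().splitlines(), strict)
    elif format == "mol":
        mol = Chem.MolFromMolFile(str(path))
        if mol is None:
            if strict:
                raise ValueError(f"unparseable MOL file: {path}")
            logger.warning("unparseable MOL file: %s", path)
        else:
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            parsed = [(name or "cpd_1", mol)]
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                msg = f"record {i}: unparseable SDF entry"
                if strict:
                    raise ValueError(msg)
                logger.warning("skipping %s", msg)
                continue
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            parsed.append((name or f"cpd_{i}", mol))

    if not parsed:
        raise ValueError(f"no parseable molecules in {path}")
    records = [
        CompoundRecord(compound_id=cid, name=cid, mol=mol, source_format=format)
        for cid, mol in parsed
    ]
    return CompoundSet(records)


def _element_multisets_intersect(a: Chem.Mol, b: Chem.Mol) -> bool:
    ea = {at.GetAtomicNum() for at in a.GetAtoms()}
    eb = {at.GetAtomicNum() for at in b.GetAtoms()}
    return bool(ea & eb)


def mcs_overlap(a: CompoundRecord, b: CompoundRecord, params: McsParams | None = None) -> McsResult:
    """Overlap coefficient ``n / min(c1, c2)`` from the connected MCS.

    ``n`` is the heavy-atom count of the maximum common connected
    substructure under the matching rules in ``params``.  Disjoint atom-type
    sets give coefficient 0.0 (logged) rather than an error.  Symmetric under
    argument swap.
    """
    params = params or McsParams()
    c1, c2 = a.n_heavy_atoms, b.n_heavy_atoms
    if c1 < 1 or c2 < 1:
        raise ValueError("both molecules must have at least one heavy atom")

    if params.atom_compare == "elements" and not _element_multisets_intersect(a.mol, b.mol):
        logger.info(
            "compounds %s and %s share no atom type: overlap coefficient 0.0",
            a.compound_id, b.compound_id,
        )
        return McsResult(n=0, c1=c1, c2=c2, coefficient=0.0)

    res = params._find_mcs([a.mol, b.mol])
    n = res.numAtoms
    if n < 1:
        # rdFMCS needs at least one mapped bond; a single shared atom type
        # still counts as a 1-atom common substructure
        n = 1
    if res.canceled:
        logger.warning(
            "MCS search for %s vs %s timed out after %.3gs; using best-so-far size %d",
            a.compound_id, b.compound_id, params.timeout_s, n,
        )
    return McsResult(
        n=n, c1=c1, c2=c2, coefficient=n / min(c1, c2), timed_out=bool(res.canceled)
    )


def tanimoto_sets(a: set, b: set) -> float:
    """Tanimoto coefficient of two feature sets: |A∩B| / |A∪B| (0.0 if both empty)."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def morgan_tanimoto(
    a: CompoundRecord, b: CompoundRecord, radius: int = 2, n_bits: int = 2048
) -> float:
    """Tanimoto similarity of hashed Morgan (ECFP-like) fingerprints."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if n_bits < 2 or n_bits & (n_bits - 1):
        raise ValueError("n_bits must be a power of two")
    if a.n_heavy_atoms < 1 or b.n_heavy_atoms < 1:
        raise ValueError("both molecules must have at least one heavy atom")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fa, fb = gen.GetFingerprint(a.mol), gen.GetFingerprint(b.mol)
    return DataStructs.TanimotoSimilarity(fa, fb)


@dataclass
class SimilarityMatrix:
    """Symmetric compound x compound similarity matrix, diagonal 1.0."""

    labels: list[str]
    values: np.ndarray
    method: str  # mcs_overlap | morgan_tanimoto

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path: str | Path, method: str = "unknown") -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float), method=method)


def similarity_matrix(
    compound_set: CompoundSet,
    method: str = "mcs_overlap",
    params: McsParams | None = None,
    radius: int = 2,
    n_bits: int = 2048,
) -> SimilarityMatrix:
    """Pairwise similarity over all compounds; each unordered pair computed once.

    The diagonal is forced to 1.0 and the matrix mirrored; row/column order is
    the set order.  A failing pair propagates with both compound ids named.
    """
    if len(compound_set) < 2:
        raise ValueError("need at least 2 compounds for a similarity matrix")
    if method not in {"mcs_overlap", "morgan_tanimoto"}:
        raise ValueError(f"unknown similarity method {method!r}")
    n = len(compound_set)
    values = np.eye(n)
    recs = compound_set.records
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if method == "mcs_overlap":
                    s = mcs_overlap(recs[i], recs[j], params).coefficient
                else:
                    s = morgan_tanimoto(recs[i], recs[j], radius=radius, n_bits=n_bits)
            except Exception as exc:
                raise RuntimeError(
                    f"similarity failed for pair "
                    f"({recs[i].compound_id}, {recs[j].compound_id}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(labels=compound_set.ids, values=values, method=method)
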
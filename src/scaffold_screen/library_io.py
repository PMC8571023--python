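"""Drug-library I/O and scaffold substructure filtering.

A screening library is a list of :class:`MoleculeRecord` read from SMILES
(``.smi``), SDF or CSV. The screen itself is a plain substructure search: a
:class:`ScaffoldQuery` (SMARTS) is matched against each library entry after
salt stripping, and the matching records form the hit set.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# Quiet RDKit's per-molecule parse warnings; unparseable entries are counted
# and reported by read_library instead.
RDLogger.DisableLog("rdApp.error")

#: Propane-1-sulfonic acid core: a three-carbon aliphatic chain bonded to a
#: sulfonate/sulfonic-acid group. The terminal oxygen primitive accepts both
#: the protonated (-S(=O)(=O)OH) and anionic (-S(=O)(=O)[O-]) forms.
DEFAULT_SCAFFOLD_SMARTS = "CCCS(=O)(=O)[OX1,OX2]"

#: Reference structure the default query must embed in (its own scaffold).
PROPANESULFONIC_ACID_SMILES = "CCCS(=O)(=O)O"


@dataclass
class MoleculeRecord:
    """One library entry: identifier, structure and provenance."""

    id: str
    name: str
    smiles: str
    mol: Chem.Mol
    source: str = ""

    @classmethod
    def from_smiles(cls, smiles: str, id: str, name: str = "",
                    source: str = "") -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            raise ValueError(f"unparseable or empty SMILES for {id!r}: {smiles!r}")
        return cls(id=id, name=name or id, smiles=Chem.MolToSmiles(mol),
                   mol=mol, source=source)


@dataclass
class ScaffoldQuery:
    """A named substructure query in SMARTS, with a reference structure the
    pattern must match (a self-consistency guard against typo'd SMARTS)."""

    name: str = "propanesulfonic"
    pattern: str = DEFAULT_SCAFFOLD_SMARTS
    reference_smiles: str = PROPANESULFONIC_ACID_SMILES
    query_mol: Chem.Mol = field(init=False, repr=False)

    def __post_init__(self) -> None:
        query = Chem.MolFromSmarts(self.pattern)
        if query is None:
            raise ValueError(f"SMARTS pattern does not compile: {self.pattern!r}")
        ref = Chem.MolFromSmiles(self.reference_smiles)
        if ref is None:
            raise ValueError(f"reference SMILES does not parse: {self.reference_smiles!r}")
        if not ref.HasSubstructMatch(query):
            raise ValueError(
                f"pattern {self.pattern!r} does not match its own reference "
                f"structure {self.reference_smiles!r}")
        self.query_mol = query


@dataclass
class LibraryLoad:
    """Result of reading a library file: parsed records plus a skip report."""

    records: list[MoleculeRecord]
    n_skipped: int = 0
    skipped: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"smi", "sdf", "csv"}:
        return suffix
    raise ValueError(f"cannot infer library format from suffix {path.suffix!r}; "
                     "pass format='smi'|'sdf'|'csv'")


def read_library(path: str | Path, format: str | None = None) -> LibraryLoad:
    """Read a drug library from ``.smi``, SDF (V2000) or CSV.

    Unparseable entries are skipped and counted (``LibraryLoad.n_skipped``).
    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` when no
    record parses or when two records share an id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"library file not found: {path}")
    fmt = format or _infer_format(path)
    source = str(path)

    records: list[MoleculeRecord] = []
    skipped: list[str] = []

    if fmt == "smi":
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"M{i}"
            try:
                records.append(MoleculeRecord.from_smiles(smiles, id=name,
                                                          name=name, source=source))
            except ValueError:
                skipped.append(f"line {i}: {smiles}")
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier, start=1):
            if mol is None or mol.GetNumHeavyAtoms() == 0:
                skipped.append(f"record {i}")
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            rec_id = name or f"M{i}"
            records.append(MoleculeRecord(id=rec_id, name=name or rec_id,
                                          smiles=Chem.MolToSmiles(mol),
                                          mol=mol, source=source))
    elif fmt == "csv":
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
                raise ValueError("library CSV requires a header with columns id,smiles")
            for i, row in enumerate(reader, start=2):
                try:
                    records.append(MoleculeRecord.from_smiles(
                        row["smiles"], id=row["id"],
                        name=row.get("name") or row["id"], source=source))
                except ValueError:
                    skipped.append(f"line {i}: {row.get('smiles')!r}")
    else:
        raise ValueError(f"unknown library format: {fmt!r}")

    if not records:
        raise ValueError(f"zero parseable records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in library: {dupes}")
    if skipped:
        logger.warning("skipped %d unparseable entries in %s", len(skipped), path)
    return LibraryLoad(records=records, n_skipped=len(skipped), skipped=skipped)


def strip_salts(record: MoleculeRecord) -> MoleculeRecord:
    """Return the largest covalently connected component of a record.

    Counter-ions and minor salt components are dropped; single-component
    input is returned unchanged. Ties on heavy-atom count keep the first
    component. Idempotent.
    """
    frags = Chem.GetMolFrags(record.mol, asMols=True, sanitizeFrags=True)
    if len(frags) <= 1:
        return record
    largest = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return replace(record, mol=largest, smiles=Chem.MolToSmiles(largest))


def count_scaffold_matches(record: MoleculeRecord, query: ScaffoldQuery) -> int:
    """Number of distinct embeddings of the query in the salt-stripped record."""
    stripped = strip_salts(record)
    return len(stripped.mol.GetSubstructMatches(query.query_mol, uniquify=True))


def scaffold_filter(library: Iterable[MoleculeRecord],
                    query: ScaffoldQuery | None = None) -> list[MoleculeRecord]:
    """Return the records containing >=1 embedding of the scaffold pattern.

    Matching is performed on the salt-stripped structure; the returned
    records are the original (unstripped) entries in input order.
    """
    query = query or ScaffoldQuery()
    return [rec for rec in library
            if strip_salts(rec).mol.HasSubstructMatch(query.query_mol)]


def write_hits(hits: Sequence[MoleculeRecord], query: ScaffoldQuery,
               path: str | Path) -> None:
    """Write the hit set as CSV with columns id,name,smiles,n_matches."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "name", "smiles", "n_matches"])
        for rec in hits:
            writer.writerow([rec.id, rec.name, rec.smiles,
                             count_scaffold_matches(rec, query)])
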
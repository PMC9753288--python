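"""Reading, validating and tag-filtering compound libraries.

Compound libraries arrive either as a simple CSV dialect
(``compound_id,smiles,name,tags`` with ``;``-separated tags) or as an SDF
(CTAB V2000, compound id taken from the molecule title line).  Every
structure is canonicalized on ingestion so that downstream descriptor
computation and deduplication are deterministic.  Salts and mixtures are
reduced to the largest covalent fragment before canonicalization;
stereochemistry is retained in the stored SMILES but plays no role in the
purely topological descriptors used elsewhere in this package.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

from rdkit import Chem, RDLogger

log = logging.getLogger(__name__)

# RDKit is chatty about every unparseable SMILES; we log rejections ourselves.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "CompoundRecord",
    "CompoundLibrary",
    "canonicalize",
    "parse_library",
    "write_library",
    "filter_by_tags",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule with an opaque id, canonical SMILES and annotation tags."""

    compound_id: str
    smiles: str
    name: str = ""
    tags: frozenset[str] = field(default_factory=frozenset)
    source: str = ""


@dataclass
class CompoundLibrary:
    """Ordered collection of :class:`CompoundRecord` with unique ids."""

    records: list[CompoundRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.compound_id in seen:
                raise ValueError(f"duplicate compound_id: {rec.compound_id!r}")
            seen.add(rec.compound_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def get(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    def smiles_map(self) -> dict[str, str]:
        return {r.compound_id: r.smiles for r in self.records}


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES of the largest covalent fragment.

    Idempotent; two SMILES spellings of the same molecular graph map to the
    same output.  Raises ``ValueError`` for unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(_largest_fragment(mol))


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES into an RDKit Mol, raising ``ValueError`` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def _normalize_tags(raw: str | set | frozenset | None) -> frozenset[str]:
    if raw is None:
        return frozenset()
    if isinstance(raw, str):
        parts = raw.split(";")
    else:
        parts = list(raw)
    return frozenset(p.strip().lower() for p in parts if p and p.strip())


def _parse_smiles_csv(path: str) -> tuple[list[CompoundRecord], int]:
    records: list[CompoundRecord] = []
    n_rejected = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header row with a 'smiles' column")
        for i, row in enumerate(reader):
            cid = (row.get("compound_id") or f"row{i}").strip()
            try:
                smi = canonicalize(row["smiles"])
            except (ValueError, KeyError, TypeError):
                log.warning("rejecting %s: unparseable SMILES %r", cid, row.get("smiles"))
                n_rejected += 1
                continue
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    smiles=smi,
                    name=(row.get("name") or "").strip(),
                    tags=_normalize_tags(row.get("tags")),
                    source=path,
                )
            )
    return records, n_rejected


def _parse_sdf(path: str) -> tuple[list[CompoundRecord], int]:
    records: list[CompoundRecord] = []
    n_rejected = 0
    supplier = Chem.SDMolSupplier(path, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("rejecting SDF entry %d: unparseable molblock", i)
            n_rejected += 1
            continue
        cid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not cid:
            cid = f"sdf{i}"
        tags = _normalize_tags(mol.GetProp("tags")) if mol.HasProp("tags") else frozenset()
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=Chem.MolToSmiles(_largest_fragment(mol)),
                name=mol.GetProp("name") if mol.HasProp("name") else cid,
                tags=tags,
                source=path,
            )
        )
    return records, n_rejected


def parse_library(path: str, format: str = "smiles-csv") -> CompoundLibrary:
    """Read a compound library from ``smiles-csv`` or ``sdf``.

    Unparseable entries are skipped, logged, and counted in
    ``metadata["n_rejected"]``.  Zero parseable records is a format error.
    """
    if format == "smiles-csv":
        records, n_rejected = _parse_smiles_csv(path)
    elif format == "sdf":
        records, n_rejected = _parse_sdf(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'smiles-csv' or 'sdf'")
    if not records:
        raise ValueError(f"{path}: no parseable records ({n_rejected} rejected)")
    return CompoundLibrary(records, metadata={"path": path, "n_rejected": n_rejected})


def write_library(library: CompoundLibrary, path: str) -> None:
    """Write a library back to the smiles-csv dialect (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "smiles", "name", "tags"])
        for rec in library:
            writer.writerow([rec.compound_id, rec.smiles, rec.name, ";".join(sorted(rec.tags))])


def filter_by_tags(library: CompoundLibrary, required_tags: set[str]) -> CompoundLibrary:
    """Keep exactly the records whose tag set contains every required tag.

    Matching is case-insensitive exact string match after trimming; there is
    no synonym expansion.  An empty ``required_tags`` would be a no-op filter
    and raises ``ValueError``.
    """
    required = _normalize_tags(required_tags)
    if not required:
        raise ValueError("required_tags must be non-empty")
    kept = [rec for rec in library if required <= rec.tags]
    meta = dict(library.metadata)
    meta["tag_filter"] = sorted(required)
    return CompoundLibrary(kept, metadata=meta)


def retag(record: CompoundRecord, tags: set[str]) -> CompoundRecord:
    return replace(record, tags=_normalize_tags(tags))
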
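"""Bioactivity record curation and binary activity labeling.

Raw potency records (compound, target, measure, value, units) emulating
ChEMBL/BindingDB exports are reduced to a one-row-per-compound modeling
dataset in three steps:

1. ``curate`` — keep only IC50/Ki records whose compound has a resolvable
   structure and a positive, unit-recognized value; convert everything to nM.
2. ``deduplicate`` — collapse replicate records per compound to their
   unweighted arithmetic mean (IC50 and Ki pooled, linear nM scale).
3. ``label`` — binary split at a configurable potency cutoff
   (default 1000 nM = 1 µM); strictly-below-cutoff is active.

Drops are never silent: each is logged with a reason code and the per-reason
counts are returned so that input/output record counts always reconcile.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .compound_io import CompoundLibrary

log = logging.getLogger(__name__)

ALLOWED_MEASURES = frozenset({"IC50", "Ki"})

#: conversion factors to nanomolar
UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "mM": 1e6, "M": 1e9}

DEFAULT_CUTOFF_NM = 1000.0


@dataclass(frozen=True)
class BioactivityRecord:
    compound_id: str
    target_id: str
    measure: str  # "IC50", "Ki" or anything else (dropped by curate)
    value: float
    units: str
    source_db: str = ""
    record_id: str = ""


@dataclass
class LabeledEntry:
    compound_id: str
    smiles: str
    mean_activity_nm: float
    label: str  # "active" | "inactive"
    provenance: list[str] = field(default_factory=list)


@dataclass
class LabeledDataset:
    entries: list[LabeledEntry]
    cutoff_nm: float

    @property
    def n_active(self) -> int:
        return sum(e.label == "active" for e in self.entries)

    @property
    def n_inactive(self) -> int:
        return sum(e.label == "inactive" for e in self.entries)

    def labels(self) -> list[int]:
        return [1 if e.label == "active" else 0 for e in self.entries]

    def ids(self) -> list[str]:
        return [e.compound_id for e in self.entries]

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["compound_id", "smiles", "mean_activity_nM", "label"])
            for e in self.entries:
                w.writerow([e.compound_id, e.smiles, f"{e.mean_activity_nm:.6g}", e.label])


def curate(
    records: list[BioactivityRecord],
    structures: CompoundLibrary,
    drop_counts: Counter | None = None,
) -> list[BioactivityRecord]:
    """Filter raw records to usable IC50/Ki entries, all converted to nM.

    Records are dropped (with a logged reason code) when the measure is not
    IC50/Ki (``wrong-measure``), the compound has no structure in
    ``structures`` (``no-structure``), the value is missing or non-positive
    (``bad-value``), or the units are unrecognized (``bad-units``).
    ``drop_counts``, when supplied, receives per-reason counts so callers can
    check conservation: dropped + retained == input.
    """
    known_ids = set(structures.ids())
    out: list[BioactivityRecord] = []
    counts: Counter = drop_counts if drop_counts is not None else Counter()
    for rec in records:
        if rec.measure not in ALLOWED_MEASURES:
            counts["wrong-measure"] += 1
            log.debug("drop %s: wrong-measure (%s)", rec.compound_id, rec.measure)
            continue
        if rec.compound_id not in known_ids:
            counts["no-structure"] += 1
            log.debug("drop %s: no-structure", rec.compound_id)
            continue
        if rec.value is None or not (rec.value > 0):
            counts["bad-value"] += 1
            log.debug("drop %s: bad-value (%r)", rec.compound_id, rec.value)
            continue
        if rec.units not in UNIT_TO_NM:
            counts["bad-units"] += 1
            log.debug("drop %s: bad-units (%r)", rec.compound_id, rec.units)
            continue
        out.append(
            BioactivityRecord(
                compound_id=rec.compound_id,
                target_id=rec.target_id,
                measure=rec.measure,
                value=rec.value * UNIT_TO_NM[rec.units],
                units="nM",
                source_db=rec.source_db,
                record_id=rec.record_id,
            )
        )
    return out


def deduplicate(records: list[BioactivityRecord]) -> list[tuple[str, float, list[str]]]:
    """Collapse curated records to one ``(compound_id, mean_nM, provenance)``
    per compound using the unweighted arithmetic mean on the nM scale.

    IC50 and Ki values are pooled without conversion.  Output order follows
    first appearance of each compound; the mean is permutation-invariant.
    """
    values: dict[str, list[float]] = defaultdict(list)
    prov: dict[str, list[str]] = defaultdict(list)
    order: list[str] = []
    for rec in records:
        if rec.units != "nM":
            raise ValueError("deduplicate expects curated records in nM")
        if rec.compound_id not in values:
            order.append(rec.compound_id)
        values[rec.compound_id].append(rec.value)
        prov[rec.compound_id].append(rec.record_id or f"{rec.source_db}:{rec.measure}")
    return [(cid, sum(values[cid]) / len(values[cid]), prov[cid]) for cid in order]


def label(
    entries: list[tuple[str, float, list[str]]] | list[tuple[str, float]],
    structures: CompoundLibrary,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
) -> LabeledDataset:
    """Binary-label deduplicated entries: active iff mean potency < cutoff.

    The boundary is exclusive by documented convention: a compound exactly at
    the cutoff is inactive.  Raising the cutoff can only move compounds from
    inactive to active (monotone).
    """
    if not cutoff_nm > 0:
        raise ValueError("cutoff_nm must be positive")
    smiles = structures.smiles_map()
    out: list[LabeledEntry] = []
    for entry in entries:
        cid, mean_nm = entry[0], entry[1]
        prov = list(entry[2]) if len(entry) > 2 else []
        out.append(
            LabeledEntry(
                compound_id=cid,
                smiles=smiles.get(cid, ""),
                mean_activity_nm=mean_nm,
                label="active" if mean_nm < cutoff_nm else "inactive",
                provenance=prov,
            )
        )
    ds = LabeledDataset(out, cutoff_nm=cutoff_nm)
    log.info("labeled %d compounds: %d active / %d inactive (cutoff %g nM)",
             len(out), ds.n_active, ds.n_inactive, cutoff_nm)
    return ds


def build_dataset(
    records: list[BioactivityRecord],
    structures: CompoundLibrary,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
) -> LabeledDataset:
    """Convenience: curate → deduplicate → label in one call."""
    return label(deduplicate(curate(records, structures)), structures, cutoff_nm)


def read_bioactivity_csv(path: str) -> list[BioactivityRecord]:
    """Read records from CSV columns compound_id,target_id,measure,value,units,source_db."""
    out: list[BioactivityRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            try:
                value = float(row["value"])
            except (TypeError, ValueError):
                value = float("nan")
            out.append(
                BioactivityRecord(
                    compound_id=row["compound_id"].strip(),
                    target_id=(row.get("target_id") or "").strip(),
                    measure=(row.get("measure") or "").strip(),
                    value=value,
                    units=(row.get("units") or "").strip(),
                    source_db=(row.get("source_db") or "").strip(),
                    record_id=f"{path}:{i}",
                )
            )
    return out


def write_bioactivity_csv(records: list[BioactivityRecord], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "measure", "value", "units", "source_db"])
        for r in records:
            w.writerow([r.compound_id, r.target_id, r.measure, f"{r.value:.6g}", r.units, r.source_db])
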
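"""Compound-activity record parsing and curation.

Raw bioactivity tables (from a file or a ChEMBL-style service) are turned
into a deduplicated, desalted, single-activity-type dataset ready for
featurization.  Curation applies, in order:

1. keep only the requested activity type,
2. drop records with absent or non-positive activity values
   (the downstream log-scaling of activities requires a positive value),
3. canonicalize each structure and strip salts / co-crystallised fragments
   by keeping the largest organic fragment,
4. deduplicate by canonical structure, preferring the most recent
   measurement.

Every dropped record is counted in the curation log so that
``sum(drops) + len(output) == len(input)`` always holds.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger

from .errors import ConfigurationError, EmptyDatasetError, InputError

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparsable SMILES; rejections are reported
# through the curation log instead.
RDLogger.DisableLog("rdApp.error")

REQUIRED_CSV_COLUMNS = ("compound_id", "smiles", "activity_type", "activity_value")

# log keys that correspond to removed records (``desalted`` is a rewrite
# counter, not a drop): sum of these + surviving records == input records
DROP_RULES = (
    "dropped_activity_type",
    "dropped_missing",
    "rejected_invalid_structure",
    "rejected_inorganic_only",
    "deduplicated",
)


@dataclass(frozen=True)
class CompoundRecord:
    """One compound-activity measurement.

    ``activity_value`` is assumed to be a concentration in nM (Ki, Kd,
    IC50, EC50, AC50 ...); ``None`` marks a missing/unparsable value.
    """

    compound_id: str
    smiles: str
    activity_type: str
    activity_value: float | None
    year: int | None = None
    assay_description: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


@dataclass(frozen=True)
class Rejection:
    """A structure rejected during standardization, with a reason code."""

    record: CompoundRecord
    reason: str  # "invalid_structure" | "inorganic_only"


@dataclass
class CuratedDataset:
    """Curated records plus per-rule accounting of what was dropped."""

    records: list[CompoundRecord]
    curation_log: dict[str, int] = field(default_factory=dict)

    def log_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.curation_log), "count": list(self.curation_log.values())}
        )


def _to_float(value) -> float | None:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(out):
        return None
    return out


def _to_year(value) -> int | None:
    v = _to_float(value)
    return int(v) if v is not None else None


def parse_input(path: str | Path, format: str = "csv") -> list[CompoundRecord]:
    """Read compound records from a CSV, SMILES (.smi) or SDF file.

    Unparsable activity values become absent values (dropped later during
    curation, never silently coerced).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if format == "csv":
        return _parse_csv(path)
    if format == "smi":
        return _parse_smi(path)
    if format == "sdf":
        return _parse_sdf(path)
    raise ConfigurationError(f"unknown input format: {format!r}")


def _parse_csv(path: Path) -> list[CompoundRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in REQUIRED_CSV_COLUMNS:
            if col not in header:
                raise ConfigurationError(f"CSV input lacks required column {col!r}")
        records = []
        for row in reader:
            records.append(
                CompoundRecord(
                    compound_id=row["compound_id"],
                    smiles=row["smiles"] or "",
                    activity_type=row["activity_type"] or "",
                    activity_value=_to_float(row["activity_value"]),
                    year=_to_year(row.get("year")),
                    assay_description=row.get("assay_description") or None,
                )
            )
    return records


def _parse_smi(path: Path) -> list[CompoundRecord]:
    # One structure per line, optional whitespace-separated id.  No
    # activities are carried: records get absent values and a blank type,
    # useful only for featurization demos.
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            records.append(
                CompoundRecord(
                    compound_id=cid, smiles=smiles, activity_type="", activity_value=None
                )
            )
    return records


def _parse_sdf(path: Path) -> list[CompoundRecord]:
    supplier = Chem.SDMolSupplier(str(path))
    records = []
    for i, mol in enumerate(supplier):
        if mol is None:
            # keep a placeholder so downstream rejection accounting sees it
            records.append(
                CompoundRecord(
                    compound_id=f"sdf{i + 1}",
                    smiles="",
                    activity_type="",
                    activity_value=None,
                )
            )
            continue
        props = mol.GetPropsAsDict()
        cid = props.get("compound_id") or (
            mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i + 1}"
        )
        records.append(
            CompoundRecord(
                compound_id=str(cid),
                smiles=Chem.MolToSmiles(mol),
                activity_type=str(props.get("activity_type", "")),
                activity_value=_to_float(props.get("activity_value")),
                year=_to_year(props.get("year")),
            )
        )
    return records


def canonicalize_and_desalt(record: CompoundRecord) -> CompoundRecord | Rejection:
    """Replace the structure by the canonical SMILES of its largest organic fragment.

    Multi-fragment inputs (salts, solvates) are reduced to the fragment with
    the most heavy atoms among those containing carbon; ties keep the first.
    Returns a :class:`Rejection` for unparsable or carbon-free structures.
    """
    if not record.smiles:
        return Rejection(record, "invalid_structure")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return Rejection(record, "invalid_structure")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        return Rejection(record, "inorganic_only")
    parent = max(organic, key=lambda f: f.GetNumHeavyAtoms())
    return replace(record, smiles=Chem.MolToSmiles(parent))


def _pick_duplicate(group: list[tuple[int, CompoundRecord]]) -> tuple[int, CompoundRecord]:
    """Resolve a duplicate-structure group to one representative.

    The record with the unique most recent year wins.  If the most recent
    year is tied (or no record has a year) the representative is the
    median-activity record among the candidates; for an even-sized
    candidate set, the lower-input-index of the two middle records.
    """
    years = [rec.year for _, rec in group if rec.year is not None]
    if years:
        top = max(years)
        candidates = [(i, rec) for i, rec in group if rec.year == top]
    else:
        candidates = group
    if len(candidates) == 1:
        return candidates[0]
    by_activity = sorted(candidates, key=lambda item: (item[1].activity_value, item[0]))
    m = len(by_activity)
    if m % 2 == 1:
        return by_activity[m // 2]
    a, b = by_activity[m // 2 - 1], by_activity[m // 2]
    return a if a[0] < b[0] else b


def curate(records: list[CompoundRecord], requested_activity_type: str) -> CuratedDataset:
    """Apply the full curation cascade for one activity type.

    Raises :class:`EmptyDatasetError` when nothing survives, so the
    pipeline halts with a diagnostic instead of fitting on nothing.
    """
    if not requested_activity_type:
        raise ConfigurationError("requested_activity_type must be non-empty")

    log = {
        "dropped_activity_type": 0,
        "dropped_missing": 0,
        "rejected_invalid_structure": 0,
        "rejected_inorganic_only": 0,
        "desalted": 0,
        "deduplicated": 0,
    }

    stage = [r for r in records if r.activity_type == requested_activity_type]
    log["dropped_activity_type"] = len(records) - len(stage)

    kept = [r for r in stage if r.activity_value is not None and r.activity_value > 0]
    log["dropped_missing"] = len(stage) - len(kept)

    standardized: list[CompoundRecord] = []
    for rec in kept:
        out = canonicalize_and_desalt(rec)
        if isinstance(out, Rejection):
            log[f"rejected_{out.reason}"] += 1
            continue
        if "." in rec.smiles or out.smiles != rec.smiles:
            # count any structure that was actually rewritten
            if "." in rec.smiles:
                log["desalted"] += 1
        standardized.append(out)

    groups: dict[str, list[tuple[int, CompoundRecord]]] = {}
    order: list[str] = []
    for i, rec in enumerate(standardized):
        if rec.smiles not in groups:
            groups[rec.smiles] = []
            order.append(rec.smiles)
        groups[rec.smiles].append((i, rec))

    final = []
    for smi in order:
        group = groups[smi]
        _, winner = _pick_duplicate(group)
        log["deduplicated"] += len(group) - 1
        final.append(winner)

    if not final:
        raise EmptyDatasetError(
            f"no records survive curation for activity type {requested_activity_type!r} "
            f"(log: {log})"
        )
    logger.info("curation kept %d/%d records: %s", len(final), len(records), log)
    return CuratedDataset(records=final, curation_log=log)
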
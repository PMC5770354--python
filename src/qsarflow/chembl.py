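"""ChEMBL-style bioactivity retrieval for the fully-automated input mode.

A target is identified by UniProt accession (or a CHEMBL target id) plus
an activity type.  The activity listing is either fetched from a REST
endpoint or read from a saved JSON payload; all network use is isolated
in :func:`fetch_bioactivities`.  Only entries reported in nM are kept:
the downstream activity scaling interprets its 1 / 10,000 cut-offs on a
fixed nM concentration scale, so other units are logged and skipped
rather than silently mixed in.
"""

from __future__ import annotations

import json
import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path

from .curation import CompoundRecord, _to_float, _to_year
from .errors import InputError, NotFoundError

logger = logging.getLogger(__name__)

_ACCESSION_RE = re.compile(r"^[A-Za-z0-9]{6,10}$")
_CHEMBL_ID_RE = re.compile(r"^CHEMBL\d+$")

ACCEPTED_UNITS = ("nM",)


@dataclass(frozen=True)
class TargetQuery:
    uniprot_id: str
    activity_type: str
    organism_filter: str | None = None

    def __post_init__(self) -> None:
        if not (_ACCESSION_RE.match(self.uniprot_id) or _CHEMBL_ID_RE.match(self.uniprot_id)):
            raise ValueError(
                f"{self.uniprot_id!r} is neither a UniProt accession nor a ChEMBL target id"
            )


def fetch_bioactivities(query: TargetQuery, endpoint: str | Path) -> list[dict]:
    """Return the raw activity listing for a target, untouched.

    ``endpoint`` is either an ``http(s)://`` URL of a ChEMBL-style activity
    resource or the path of a saved JSON response (the offline fixture path
    used in tests).  The payload may be a bare list of activity entries or
    an object with an ``activities`` key.
    """
    if isinstance(endpoint, str) and endpoint.startswith(("http://", "https://")):
        url = f"{endpoint.rstrip('/')}?target={query.uniprot_id}&type={query.activity_type}"
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                payload = json.loads(resp.read().decode("utf-8"))
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise NotFoundError(f"unknown accession {query.uniprot_id!r} at {endpoint}")
            raise InputError(f"request to {endpoint} failed: {exc}") from exc
        except urllib.error.URLError as exc:
            raise InputError(f"could not reach {endpoint}: {exc}") from exc
    else:
        path = Path(endpoint)
        if not path.exists():
            raise InputError(f"fixture payload not found: {path}")
        payload = json.loads(path.read_text(encoding="utf-8"))

    if isinstance(payload, dict):
        payload = payload.get("activities", [])
    if not isinstance(payload, list):
        raise InputError("activity payload is neither a list nor an object with 'activities'")
    return payload


def parse_chembl_payload(payload: list[dict], strict: bool = False) -> list[CompoundRecord]:
    """Map ChEMBL activity entries onto :class:`CompoundRecord`.

    Entries missing ``canonical_smiles`` or ``standard_value`` still yield
    records (with absent fields) so curation can account for them; entries
    with non-nM ``standard_units`` or without a molecule id are skipped and
    logged.  With ``strict=True`` a malformed entry raises instead.
    """
    records: list[CompoundRecord] = []
    skipped = 0
    for i, entry in enumerate(payload):
        if not isinstance(entry, dict):
            if strict:
                raise InputError(f"malformed payload entry at index {i}")
            logger.warning("skipping malformed payload entry %d", i)
            skipped += 1
            continue
        cid = entry.get("molecule_chembl_id")
        if not cid:
            if strict:
                raise InputError(f"payload entry {i} lacks molecule_chembl_id")
            logger.warning("skipping entry %d without molecule id", i)
            skipped += 1
            continue
        units = entry.get("standard_units")
        value = _to_float(entry.get("standard_value"))
        if value is not None and units is not None and units not in ACCEPTED_UNITS:
            logger.info("skipping entry %d (%s): units %r not in %s", i, cid, units, ACCEPTED_UNITS)
            skipped += 1
            continue
        records.append(
            CompoundRecord(
                compound_id=str(cid),
                smiles=entry.get("canonical_smiles") or "",
                activity_type=str(entry.get("standard_type", "")),
                activity_value=value,
                year=_to_year(entry.get("document_year")),
                assay_description=entry.get("assay_description"),
            )
        )
    logger.info("parsed %d records, skipped %d of %d entries", len(records), skipped, len(payload))
    return records
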
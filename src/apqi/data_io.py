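"""Reading, validating and linking encounter-level prescribing records.

The input is delimited text with one row per consultation:

======== ============= =====================================================
column    type          notes
======== ============= =====================================================
site_id   string        identifier of the out-of-hours cooperative
encounter_id string     unique within a site
date      ISO-8601 date
age_years number ≥ 0    completed years; fractional allowed for infants
sex       F / M / U
icpc      list          semicolon-separated ICPC-2 codes; empty = missing
atc       list          semicolon-separated ATC codes; empty = none
======== ============= =====================================================

``read_encounters`` never silently coerces: rows that fail validation are
excluded and reported, and a missing mandatory column is a hard error.

``link_prescriptions`` flattens encounters into one row per prescription
with the diagnosis registered in the same consultation — the single source
of truth for every prescription count downstream.  When a consultation
carries several diagnoses, each prescription is linked to the first-listed
one and the encounter is flagged (``link_all=True`` instead duplicates the
link to every diagnosis, for sensitivity analysis).
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .codesets import CodeError, validate_atc, validate_icpc, is_antibiotic

__all__ = [
    "EncounterRecord",
    "LinkedPrescription",
    "ValidationReport",
    "LinkReport",
    "SchemaError",
    "COLUMNS",
    "read_encounters",
    "write_encounters",
    "link_prescriptions",
]

COLUMNS = ("site_id", "encounter_id", "date", "age_years", "sex", "icpc", "atc")

MAX_AGE = 120.0


class SchemaError(ValueError):
    """The input file does not carry the documented columns."""


@dataclass(frozen=True)
class EncounterRecord:
    """One consultation: patient attributes, zero-or-more diagnoses,
    zero-or-more prescriptions.  An empty ``diagnoses`` tuple means the
    diagnosis was not registered."""

    site_id: str
    encounter_id: str
    date: _dt.date
    age_years: float
    sex: str
    diagnoses: tuple[str, ...] = ()
    prescriptions: tuple[str, ...] = ()


@dataclass(frozen=True)
class LinkedPrescription:
    """One prescription linked to the diagnosis registered in the same
    consultation (``diagnosis=None`` when the encounter carried none)."""

    site_id: str
    encounter_id: str
    atc: str
    diagnosis: str | None
    multi_diagnosis: bool = False


@dataclass
class ValidationReport:
    """Row-level outcome of :func:`read_encounters`."""

    n_rows: int = 0
    n_valid: int = 0
    n_excluded: int = 0
    issues: list[dict] = field(default_factory=list)

    def add_issue(self, row: int, reason: str, value: str) -> None:
        self.n_excluded += 1
        self.issues.append({"row": row, "reason": reason, "value": value})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=False)


@dataclass
class LinkReport:
    """Summary of :func:`link_prescriptions`."""

    n_links: int = 0
    n_antibiotic_links: int = 0
    n_missing_diagnosis: int = 0
    n_multi_diagnosis_encounters: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=False)


def _parse_codes(cell: str, validator) -> tuple[str, ...]:
    if cell is None or cell.strip() == "":
        return ()
    return tuple(validator(c.strip()) for c in cell.split(";") if c.strip())


def _validate_row(row: dict, seen_ids: set) -> EncounterRecord:
    date = _dt.date.fromisoformat(row["date"].strip())
    age = float(row["age_years"])
    if not 0 <= age <= MAX_AGE:
        raise ValueError(f"age_years out of range: {age}")
    sex = row["sex"].strip().upper()
    if sex not in ("F", "M", "U"):
        raise ValueError(f"sex must be F, M or U, got {row['sex']!r}")
    site = row["site_id"].strip()
    enc = row["encounter_id"].strip()
    if not enc:
        raise ValueError("empty encounter_id")
    if (site, enc) in seen_ids:
        raise ValueError(f"duplicate encounter_id {enc!r} for site {site!r}")
    return EncounterRecord(
        site_id=site,
        encounter_id=enc,
        date=date,
        age_years=age,
        sex=sex,
        diagnoses=_parse_codes(row["icpc"], validate_icpc),
        prescriptions=_parse_codes(row["atc"], validate_atc),
    )


def read_encounters(
    path, *, delimiter: str | None = None
) -> tuple[list[EncounterRecord], ValidationReport]:
    """Read and validate a delimited encounter file.

    The delimiter is sniffed from the header (comma or tab) unless
    forced.  Returns the valid records plus a :class:`ValidationReport`
    listing every excluded row with its reason.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    report = ValidationReport()
    if text.strip() == "":
        raise SchemaError(f"{path}: file is empty (no header)")
    if delimiter is None:
        header_line = text.splitlines()[0]
        delimiter = "\t" if header_line.count("\t") >= header_line.count(",") else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    missing = [c for c in COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    records: list[EncounterRecord] = []
    seen: set = set()
    for i, row in enumerate(reader, start=2):  # 1-based, after header
        report.n_rows += 1
        try:
            rec = _validate_row(row, seen)
        except (ValueError, CodeError) as exc:
            report.add_issue(i, type(exc).__name__, str(exc))
            continue
        seen.add((rec.site_id, rec.encounter_id))
        records.append(rec)
        report.n_valid += 1
    return records, report


def write_encounters(records: Iterable[EncounterRecord], path, *, delimiter=",") -> None:
    """Write records in the same dialect :func:`read_encounters` accepts."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.site_id,
                    r.encounter_id,
                    r.date.isoformat(),
                    f"{r.age_years:g}",
                    r.sex,
                    ";".join(r.diagnoses),
                    ";".join(r.prescriptions),
                ]
            )


def link_prescriptions(
    records: Sequence[EncounterRecord], *, link_all: bool = False
) -> tuple[list[LinkedPrescription], LinkReport]:
    """Flatten encounters into per-prescription rows.

    Each prescription is linked to the diagnosis of its consultation;
    with no diagnosis registered the link carries ``diagnosis=None``.
    Deterministic given record order.
    """
    links: list[LinkedPrescription] = []
    rep = LinkReport()
    for rec in records:
        multi = len(rec.diagnoses) > 1
        if multi:
            rep.n_multi_diagnosis_encounters += 1
        targets: tuple[str | None, ...]
        if not rec.diagnoses:
            targets = (None,)
        elif link_all:
            targets = rec.diagnoses
        else:
            targets = (rec.diagnoses[0],)
        for atc in rec.prescriptions:
            for diag in targets:
                links.append(
                    LinkedPrescription(
                        site_id=rec.site_id,
                        encounter_id=rec.encounter_id,
                        atc=atc,
                        diagnosis=diag,
                        multi_diagnosis=multi,
                    )
                )
                rep.n_links += 1
                if is_antibiotic(atc):
                    rep.n_antibiotic_links += 1
                if diag is None:
                    rep.n_missing_diagnosis += 1
    return links, rep
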
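"""Benchmark feedback reports.

Assembles indicator results and the coverage appraisal into a single
structured report — the artifact an audit-and-feedback programme would
hand to each out-of-hours cooperative: for every indication the pooled
value, the between-site bracket, its position relative to the acceptable
range, and (optionally) the delta against an external reference table
such as an earlier study's values.

The JSON document is the single source of truth; the markdown rendering
prints exactly the numbers stored in it (classifications as text, not
colour, so reports diff cleanly).  A machine-readable schema ships in
``data/report.schema.json`` and :func:`validate_report` checks a
document against it.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .coverage import CoverageReport, IndicationRankRow
from .indicators import IndicatorResult

__all__ = [
    "build_report",
    "render_markdown",
    "validate_report",
    "load_reference_values",
]

SCHEMA_VERSION = 1


def load_reference_values(path) -> dict[str, dict]:
    """Read a reference-value table: ``{icpc: {a, b, c, source}}``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, dict] = {}
    for icpc, vals in raw.items():
        entry = {k: float(v) for k, v in vals.items() if k in ("a", "b", "c")}
        for v in entry.values():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"reference value for {icpc} outside [0,100]: {v}")
        entry["source"] = str(vals.get("source", "reference"))
        out[icpc] = entry
    return out


def _indicator_section(res: IndicatorResult, ref: Mapping | None) -> dict:
    section: dict = {
        "icpc": res.icpc,
        "label": res.label,
        "n_eligible": res.n_eligible,
        "n_ab": res.n_ab,
        "n_recommended": res.n_recommended,
        "n_quinolone": res.n_quinolone,
    }
    for key, value, cls in (
        ("a", res.a, res.class_a),
        ("b", res.b, res.class_b),
        ("c", res.c, res.class_c),
    ):
        entry: dict = {
            "value": value,
            "class": cls.value,
            "bracket": list(res.brackets[key]) if res.brackets.get(key) else None,
        }
        if ref is not None and key in ref and value is not None:
            entry["reference"] = ref[key]
            entry["delta"] = round(value - ref[key], 1)
        section[key] = entry
    section["per_site"] = {s: list(v) for s, v in res.per_site.items()}
    return section


def build_report(
    results: Sequence[IndicatorResult],
    coverage: CoverageReport,
    ranking: Sequence[IndicationRankRow] = (),
    reference: Mapping[str, Mapping] | None = None,
) -> dict:
    """Assemble the feedback report as a JSON-serializable dict.

    Reference entries whose ICPC code matches no computed indicator are
    ignored with a warning-style note in the report itself.
    """
    computed = {r.icpc for r in results}
    unknown_refs = sorted(set(reference or ()) - computed)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "indicators": [
            _indicator_section(r, (reference or {}).get(r.icpc)) for r in results
        ],
        "coverage": {
            "total_prescriptions": coverage.total_prescriptions,
            "covered_count": coverage.covered_count,
            "covered_share": coverage.covered_share,
            "n_diagnoses_for_90pct": coverage.n_diagnoses_for_90pct,
            "symptom_share": coverage.symptom_share,
            "prescribing_rate": coverage.prescribing_rate,
        },
        "chapters": [
            {"chapter": ch, "count": n, "share": share}
            for ch, (n, share) in coverage.chapter_table.items()
        ],
        "ranking": [
            {
                "code": row.code,
                "label": row.label,
                "n_prescriptions": row.n_prescriptions,
                "share": row.share,
                "cumulative_share": row.cumulative_share,
                "in_apqi_set": row.in_apqi_set,
            }
            for row in ranking
        ],
    }
    if unknown_refs:
        report["ignored_reference_codes"] = unknown_refs
    return report


def _fmt(v) -> str:
    return "-" if v is None else f"{v:.1f}"


def render_markdown(report: Mapping) -> str:
    """Human-readable rendering; every number equals its JSON field."""
    lines = ["# Antibiotic prescribing quality report", ""]
    cov = report["coverage"]
    lines += [
        f"Total antibiotic prescriptions: {cov['total_prescriptions']}",
        f"Covered by the indicator diagnoses: {cov['covered_count']} "
        f"({_fmt(cov['covered_share'])}%)",
        f"Diagnoses needed for 90% of prescriptions: "
        f"{cov['n_diagnoses_for_90pct'] if cov['n_diagnoses_for_90pct'] is not None else 'not reachable'}",
        f"Share linked to symptom diagnoses: {_fmt(cov['symptom_share'])}%",
        "",
        "## Indicators",
        "",
        "| ICPC | Indication | a (% treated) | b (% recommended) | c (% quinolone) |",
        "|---|---|---|---|---|",
    ]
    for sec in report["indicators"]:
        cells = []
        for key in "abc":
            e = sec[key]
            br = (
                f" [{_fmt(e['bracket'][0])}-{_fmt(e['bracket'][1])}]"
                if e["bracket"]
                else ""
            )
            delta = f", Δref {e['delta']:+.1f}" if "delta" in e else ""
            cells.append(f"{_fmt(e['value'])}{br} ({e['class']}{delta})")
        lines.append(f"| {sec['icpc']} | {sec['label']} | " + " | ".join(cells) + " |")
    if report.get("chapters"):
        lines += ["", "## Prescriptions by ICPC chapter", "", "| Chapter | n | % |", "|---|---|---|"]
        for row in report["chapters"]:
            lines.append(f"| {row['chapter']} | {row['count']} | {_fmt(row['share'])} |")
    if report.get("ranking"):
        lines += ["", "## Ranked indications", "", "| Code | Indication | n | % | cum % |", "|---|---|---|---|---|"]
        for row in report["ranking"]:
            mark = " †" if row["in_apqi_set"] else ""
            lines.append(
                f"| {row['code']}{mark} | {row['label']} | {row['n_prescriptions']} "
                f"| {_fmt(row['share'])} | {_fmt(row['cumulative_share'])} |"
            )
        lines.append("")
        lines.append("† indicator diagnosis")
    return "\n".join(lines) + "\n"


def _load_schema() -> dict:
    text = resources.files("apqi.data").joinpath("report.schema.json").read_text("utf-8")
    return json.loads(text)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(instance, schema, path: str, errors: list[str], root=None) -> None:
    # minimal structural validator for the shipped schema subset
    root = root if root is not None else schema
    if "$ref" in schema:
        target = root
        for part in schema["$ref"].lstrip("#/").split("/"):
            target = target[part]
        _check(instance, target, path, errors, root)
        return
    types = schema.get("type")
    if types:
        names = [types] if isinstance(types, str) else list(types)
        allowed: tuple = ()
        for name in names:
            if name == "null":
                allowed += (type(None),)
            else:
                t = _TYPES[name]
                allowed += t if isinstance(t, tuple) else (t,)
        if not isinstance(instance, allowed) or (
            isinstance(instance, bool) and bool not in allowed
        ):
            errors.append(f"{path}: expected {types}, got {type(instance).__name__}")
            return
    if isinstance(instance, dict):
        for req in schema.get("required", []):
            if req not in instance:
                errors.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}", errors, root)
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]", errors, root)


def validate_report(report: Mapping) -> list[str]:
    """Check a report against the shipped schema; returns error list
    (empty = valid)."""
    errors: list[str] = []
    _check(dict(report), _load_schema(), "$", errors)
    return errors
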
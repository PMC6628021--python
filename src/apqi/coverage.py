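"""Describing antibiotic prescribing by indication and appraising how much
of it the indicator set covers.

Three complementary views over the linked antibiotic prescriptions:

* a **chapter table** — prescriptions grouped by ICPC-2 chapter
  (respiratory, urinary, skin, ...), with prescriptions lacking a
  diagnosis kept as their own row and small chapters collapsible into
  an "other" row;
* a **ranked indication table** — one row per diagnosis above a share
  threshold (default 3 %), ordered by prescription count, with
  cumulative shares in the style of a drug-utilization 90 % (DU90%)
  profile;
* a **coverage report** — how many prescriptions the chosen indicator
  diagnoses account for, how many top-ranked diagnoses would be needed
  to reach 90 % of prescriptions (the DU90% concept transposed from
  drugs to indications), and the share linked to symptom diagnoses.

Counts are conserved everywhere: each table, including its missing and
"other" rows, sums to the total number of antibiotic links.  Coverage
shares use that same total as denominator, so prescriptions without a
diagnosis count against coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .codesets import CodeError, icpc_chapter, is_antibiotic, is_symptom_code, validate_icpc
from .data_io import LinkedPrescription

__all__ = [
    "MISSING",
    "OTHER",
    "APQI7",
    "APQI9",
    "IndicationRankRow",
    "CoverageReport",
    "antibiotic_links",
    "rank_indications",
    "chapter_table",
    "coverage_of_set",
]

#: Row keys for prescriptions without a diagnosis and for the pooled tail.
MISSING = "missing"
OTHER = "other"

#: The seven consensus indicator diagnoses.
APQI7 = frozenset({"R78", "R74", "U71", "R76", "R75", "H71", "R81"})
#: The extended set adding the proposed erysipelas and teeth/gum entries.
APQI9 = APQI7 | {"S76", "D82"}


@dataclass(frozen=True)
class IndicationRankRow:
    """One diagnosis (or the missing/other pool) in the ranked table."""

    code: str  # an ICPC code, MISSING or OTHER
    label: str
    n_prescriptions: int
    share: float  # percent of total, one decimal
    cumulative_share: float
    in_apqi_set: bool


@dataclass
class CoverageReport:
    """How well an indication set accounts for antibiotic prescribing."""

    total_prescriptions: int
    covered_count: int
    covered_share: float  # percent, one decimal
    n_diagnoses_for_90pct: int | None  # None if 90 % is unreachable
    symptom_share: float
    chapter_table: dict[str, tuple[int, float]] = field(default_factory=dict)
    prescribing_rate: float | None = None  # prescriptions per 100 encounters


def antibiotic_links(links: Iterable[LinkedPrescription]) -> list[LinkedPrescription]:
    """Restrict links to systemic antibacterial (J01) prescriptions."""
    return [l for l in links if is_antibiotic(l.atc)]


def _diagnosis_counts(ab_links: Sequence[LinkedPrescription]) -> dict[str | None, int]:
    counts: dict[str | None, int] = {}
    for l in ab_links:
        counts[l.diagnosis] = counts.get(l.diagnosis, 0) + 1
    return counts


def rank_indications(
    links: Iterable[LinkedPrescription],
    *,
    threshold: float = 3.0,
    labels: Mapping[str, str] | None = None,
    apqi_set: frozenset[str] = APQI7,
) -> list[IndicationRankRow]:
    """Rank diagnoses by antibiotic prescription count.

    Diagnoses whose share of the total is at least *threshold* percent
    get their own row; the rest are pooled into an ``other`` row placed
    last.  Prescriptions without a diagnosis form a ``missing`` row
    ranked by its own count.  Ties are broken by ICPC code ascending.
    """
    ab = antibiotic_links(links)
    total = len(ab)
    if total == 0:
        return []
    labels = labels or {}
    counts = _diagnosis_counts(ab)
    named: list[tuple[str, int]] = []
    other_count = 0
    for diag, n in counts.items():
        share = 100.0 * n / total
        if diag is None:
            named.append((MISSING, n))
        elif share >= threshold:
            named.append((diag, n))
        else:
            other_count += n
    named.sort(key=lambda kv: (-kv[1], kv[0]))
    rows: list[IndicationRankRow] = []
    cum = 0
    for code, n in named:
        cum += n
        rows.append(
            IndicationRankRow(
                code=code,
                label=labels.get(code, "Diagnosis missing" if code == MISSING else code),
                n_prescriptions=n,
                share=round(100.0 * n / total, 1),
                cumulative_share=round(100.0 * cum / total, 1),
                in_apqi_set=code in apqi_set,
            )
        )
    if other_count:
        cum += other_count
        rows.append(
            IndicationRankRow(
                code=OTHER,
                label=f"Diagnoses below {threshold:g}% each",
                n_prescriptions=other_count,
                share=round(100.0 * other_count / total, 1),
                cumulative_share=round(100.0 * cum / total, 1),
                in_apqi_set=False,
            )
        )
    return rows


def chapter_table(
    links: Iterable[LinkedPrescription],
    *,
    collapse_below: float | None = 5.0,
) -> dict[str, tuple[int, float]]:
    """Antibiotic prescriptions per ICPC-2 chapter.

    Returns ``{chapter: (count, share_percent)}`` ordered by count
    descending; prescriptions without a diagnosis stay in a ``missing``
    row.  Chapters whose share falls below *collapse_below* percent are
    pooled into an ``other`` row (pass ``None`` to keep all chapters).
    """
    ab = antibiotic_links(links)
    total = len(ab)
    if total == 0:
        return {}
    counts: dict[str, int] = {}
    for l in ab:
        key = MISSING if l.diagnosis is None else icpc_chapter(l.diagnosis)
        counts[key] = counts.get(key, 0) + 1
    kept: dict[str, int] = {}
    other = 0
    for ch, n in counts.items():
        if (
            collapse_below is not None
            and ch != MISSING
            and 100.0 * n / total < collapse_below
        ):
            other += n
        else:
            kept[ch] = n
    ordered = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    table = {ch: (n, round(100.0 * n / total, 1)) for ch, n in ordered}
    if other:
        table[OTHER] = (other, round(100.0 * other / total, 1))
    return table


def _n_for_90pct(counts: dict[str | None, int], total: int) -> int | None:
    """Minimal number of top diagnoses whose cumulative share reaches 90 %."""
    ranked = sorted(
        ((d, n) for d, n in counts.items() if d is not None),
        key=lambda kv: (-kv[1], kv[0]),
    )
    cum = 0
    for i, (_, n) in enumerate(ranked, start=1):
        cum += n
        if 100.0 * cum / total >= 90.0:
            return i
    return None


def coverage_of_set(
    links: Iterable[LinkedPrescription],
    indication_set: Iterable[str] = APQI7,
    *,
    n_encounters: int | None = None,
) -> CoverageReport:
    """Appraise how much antibiotic prescribing an indication set covers.

    ``covered_count`` is the number of antibiotic links whose diagnosis
    belongs to the set; the share denominator is *all* antibiotic links,
    including those without a diagnosis.  Syntactically invalid codes in
    the set are dropped with a warning.  ``n_encounters``, when given,
    adds the overall prescriptions-per-100-encounters rate.
    """
    valid_set: set[str] = set()
    for code in indication_set:
        try:
            valid_set.add(validate_icpc(code))
        except CodeError:
            warnings.warn(f"ignoring unknown ICPC code in indication set: {code!r}")
    ab = antibiotic_links(links)
    total = len(ab)
    counts = _diagnosis_counts(ab)
    covered = sum(n for d, n in counts.items() if d is not None and d in valid_set)
    symptom = sum(
        n for d, n in counts.items() if d is not None and is_symptom_code(d)
    )
    return CoverageReport(
        total_prescriptions=total,
        covered_count=covered,
        covered_share=round(100.0 * covered / total, 1) if total else 0.0,
        n_diagnoses_for_90pct=_n_for_90pct(counts, total) if total else None,
        symptom_share=round(100.0 * symptom / total, 1) if total else 0.0,
        chapter_table=chapter_table(ab),
        prescribing_rate=(
            round(100.0 * total / n_encounters, 1) if n_encounters else None
        ),
    )
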
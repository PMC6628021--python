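"""The disease-specific prescribing quality indicator engine.

For each configured indication three percentages are computed over the
encounters carrying that diagnosis and satisfying its age/sex
eligibility window:

* ``a`` — percentage of eligible encounters with ≥1 systemic
  antibacterial (J01) prescription,
* ``b`` — percentage of the antibiotic-treated encounters receiving a
  guideline-recommended antibiotic,
* ``c`` — percentage of the antibiotic-treated encounters receiving a
  quinolone (J01M).

``b`` and ``c`` are conditional on treatment (denominator = the treated
encounters): the benchmark ranges (>80 % recommended, <5 % quinolones)
are only coherent on that denominator.  ``conditional=False`` exposes
the unconditional variant (denominator = all eligible encounters).

Each value is classified against its acceptable range, and per-site
recomputation yields the min–max bracket that expresses between-site
variation.  Percentages are computed at full precision, classified
unrounded, and stored to one decimal; renderers display them rounded to
integers.  Encounters stand in for patients throughout: the data carry
no patient identifier, and one consultation is the natural unit of an
out-of-hours contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .codesets import (
    IndicatorDefinition,
    atc_matches,
    default_config,
    is_antibiotic,
    is_quinolone,
)
from .data_io import EncounterRecord

__all__ = [
    "RangeClass",
    "IndicatorResult",
    "is_eligible",
    "compute_indicator",
    "compute_all",
    "classify",
    "per_site_ranges",
]


class RangeClass(str, Enum):
    """Position of an indicator value relative to its acceptable range."""

    WITHIN = "WITHIN"
    ABOVE = "ABOVE"
    BELOW = "BELOW"
    UNDEFINED = "UNDEFINED"


def is_eligible(
    record: EncounterRecord,
    definition: IndicatorDefinition,
    *,
    strict_age: bool = False,
) -> bool:
    """Does the encounter enter the indicator denominator?

    Requires the indication's ICPC code among the encounter's diagnoses,
    the age inside ``[min_age, max_age]`` and the sex to match any
    restriction.  Age bounds are inclusive on completed years by
    default ("older than two years" → age ≥ 2); ``strict_age=True``
    switches the lower bound to the strict reading (> min_age).
    """
    if definition.icpc not in record.diagnoses:
        return False
    if definition.min_age is not None:
        if strict_age:
            if not record.age_years > definition.min_age:
                return False
        elif record.age_years < definition.min_age:
            return False
    if definition.max_age is not None and record.age_years > definition.max_age:
        return False
    if definition.sex is not None and record.sex != definition.sex:
        return False
    return True


def classify(value: float | None, rng: tuple[float | None, float | None]) -> RangeClass:
    """Classify an (unrounded) percentage against an acceptable range.

    The range is closed at its stated bounds; an unbounded side passes.
    ``None`` (undefined value, zero denominator) passes through.
    """
    if value is None:
        return RangeClass.UNDEFINED
    lo, hi = rng
    if lo is not None and value < lo:
        return RangeClass.BELOW
    if hi is not None and value > hi:
        return RangeClass.ABOVE
    return RangeClass.WITHIN


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def _round1(x: float | None) -> float | None:
    return None if x is None else round(x, 1)


@dataclass
class IndicatorResult:
    """Counts, percentages and classifications for one indication.

    Invariants: ``n_quinolone ≤ n_ab ≤ n_eligible`` and
    ``n_recommended ≤ n_ab``; percentages are stored to one decimal
    (``None`` when the denominator is zero); classes are computed from
    the unrounded values.
    """

    icpc: str
    label: str
    n_eligible: int
    n_ab: int
    n_recommended: int
    n_quinolone: int
    a: float | None
    b: float | None
    c: float | None
    class_a: RangeClass
    class_b: RangeClass
    class_c: RangeClass
    per_site: dict[str, tuple[float | None, float | None, float | None]] = field(
        default_factory=dict
    )
    brackets: dict[str, tuple[float, float] | None] = field(default_factory=dict)
    sites_without_eligible: list[str] = field(default_factory=list)


def _count(
    records: Sequence[EncounterRecord],
    definition: IndicatorDefinition,
    *,
    strict_age: bool,
) -> tuple[int, int, int, int]:
    n_eligible = n_ab = n_rec = n_quin = 0
    rec_set = definition.recommended
    for record in records:
        if not is_eligible(record, definition, strict_age=strict_age):
            continue
        n_eligible += 1
        abx = [p for p in record.prescriptions if is_antibiotic(p)]
        if not abx:
            continue
        n_ab += 1
        if any(atc_matches(p, rec_set) for p in abx):
            n_rec += 1
        if any(is_quinolone(p) for p in abx):
            n_quin += 1
    return n_eligible, n_ab, n_rec, n_quin


def compute_indicator(
    records: Sequence[EncounterRecord],
    definition: IndicatorDefinition,
    *,
    conditional: bool = True,
    strict_age: bool = False,
    by_site: bool = True,
) -> IndicatorResult:
    """Compute a/b/c for one indication over a record set.

    Degenerate inputs (no eligible encounters, no treated encounters)
    yield ``None`` values classified ``UNDEFINED`` — never an exception.
    With ``by_site=True`` the percentages are recomputed per site and
    min–max brackets over the sites with defined values are attached.
    """
    n_eligible, n_ab, n_rec, n_quin = _count(records, definition, strict_age=strict_age)
    a = _pct(n_ab, n_eligible)
    den_bc = n_eligible if not conditional else n_ab
    b = _pct(n_rec, den_bc)
    c = _pct(n_quin, den_bc)
    result = IndicatorResult(
        icpc=definition.icpc,
        label=definition.label,
        n_eligible=n_eligible,
        n_ab=n_ab,
        n_recommended=n_rec,
        n_quinolone=n_quin,
        a=_round1(a),
        b=_round1(b),
        c=_round1(c),
        class_a=classify(a, definition.range_a),
        class_b=classify(b, definition.range_b),
        class_c=classify(c, definition.range_c),
    )
    if by_site:
        per_site, brackets, empty = per_site_ranges(
            records, definition, conditional=conditional, strict_age=strict_age
        )
        result.per_site = per_site
        result.brackets = brackets
        result.sites_without_eligible = empty
    return result


def per_site_ranges(
    records: Sequence[EncounterRecord],
    definition: IndicatorDefinition,
    *,
    conditional: bool = True,
    strict_age: bool = False,
) -> tuple[
    dict[str, tuple[float | None, float | None, float | None]],
    dict[str, tuple[float, float] | None],
    list[str],
]:
    """Per-site (a, b, c) plus min–max brackets over defined values.

    Sites with zero eligible encounters contribute no defined values;
    they are excluded from the brackets and returned separately.
    """
    by_site: dict[str, list[EncounterRecord]] = {}
    for r in records:
        by_site.setdefault(r.site_id, []).append(r)
    per_site: dict[str, tuple[float | None, float | None, float | None]] = {}
    empty: list[str] = []
    for site in sorted(by_site):
        n_el, n_ab, n_rec, n_quin = _count(
            by_site[site], definition, strict_age=strict_age
        )
        den_bc = n_el if not conditional else n_ab
        vals = (
            _round1(_pct(n_ab, n_el)),
            _round1(_pct(n_rec, den_bc)),
            _round1(_pct(n_quin, den_bc)),
        )
        per_site[site] = vals
        if n_el == 0:
            empty.append(site)
    brackets: dict[str, tuple[float, float] | None] = {}
    for i, key in enumerate("abc"):
        defined = [v[i] for v in per_site.values() if v[i] is not None]
        brackets[key] = (min(defined), max(defined)) if defined else None
    return per_site, brackets, empty


def compute_all(
    records: Sequence[EncounterRecord],
    config: Mapping[str, IndicatorDefinition] | None = None,
    **kwargs,
) -> list[IndicatorResult]:
    """Compute every configured indicator (default: the shipped nine)."""
    config = default_config() if config is None else config
    return [compute_indicator(records, d, **kwargs) for d in config.values()]
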
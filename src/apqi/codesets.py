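"""Code systems for primary-care prescribing analysis.

Two small vocabularies underpin everything in this package:

* **ICPC-2** (International Classification of Primary Care) diagnosis
  codes — a chapter letter plus a two-digit rubric, e.g. ``"R74"`` for
  acute upper respiratory tract infection.  Rubrics 01–29 denote
  symptoms/complaints (fever, cough, ...) rather than disease entities.
* **ATC** (Anatomical Therapeutic Chemical) drug codes — hierarchical
  codes of 1/3/4/5/7 characters, e.g. ``"J01CA04"`` for amoxicillin.
  ``J01`` is the class of antibacterials for systemic use and ``J01M``
  the quinolone subgroup.

On top of the syntax checks this module carries the *indicator
configuration*: for each indication (ICPC code) an eligibility window
(age, sex), the guideline-recommended antibiotic set (ATC prefixes) and
the acceptable ranges for the three indicator percentages.  Recommended
sets are data, not code — the defaults shipped in
``data/indicators.yaml`` follow Belgian first-choice guidance and every
entry can be overridden by pointing the loader at another file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "CodeError",
    "ConfigError",
    "ICPC_CHAPTERS",
    "IndicatorDefinition",
    "validate_icpc",
    "validate_atc",
    "icpc_chapter",
    "is_symptom_code",
    "is_antibiotic",
    "is_quinolone",
    "is_recommended",
    "atc_matches",
    "load_config",
    "default_config",
]


class CodeError(ValueError):
    """A diagnosis or drug code fails its syntactic invariants."""


class ConfigError(KeyError):
    """An indication is absent from (or malformed in) the configuration."""


#: Chapter letters of ICPC-2 (no C, E, G, I, J, M, O, Q, V).
ICPC_CHAPTERS = frozenset("ABDFHKLNPRSTUWXYZ")

_ICPC_RE = re.compile(r"^([A-Z])(\d{2})$")
# ATC levels: 1 (anatomical group), 3, 4, 5, 7 characters.
_ATC_RE = re.compile(
    r"^[A-Z]$|^[A-Z]\d{2}$|^[A-Z]\d{2}[A-Z]$|^[A-Z]\d{2}[A-Z]{2}$|^[A-Z]\d{2}[A-Z]{2}\d{2}$"
)

#: Symptom/complaint rubrics occupy 01–29 in every ICPC-2 chapter.
SYMPTOM_RUBRIC_MAX = 29

ANTIBACTERIAL_PREFIX = "J01"
QUINOLONE_PREFIX = "J01M"


def validate_icpc(code: str) -> str:
    """Return *code* if it is a syntactically valid ICPC-2 code, else raise.

    Valid means: chapter letter in the ICPC-2 alphabet followed by a
    rubric 01–99 (``"R74"``, ``"U71"``, ...).
    """
    if not isinstance(code, str):
        raise CodeError(f"ICPC code must be a string, got {code!r}")
    m = _ICPC_RE.match(code)
    if not m or m.group(1) not in ICPC_CHAPTERS or int(m.group(2)) == 0:
        raise CodeError(f"invalid ICPC-2 code: {code!r}")
    return code


def validate_atc(code: str) -> str:
    """Return *code* if it has a valid ATC level structure, else raise."""
    if not isinstance(code, str):
        raise CodeError(f"ATC code must be a string, got {code!r}")
    if not _ATC_RE.match(code):
        raise CodeError(f"invalid ATC code: {code!r}")
    return code


def icpc_chapter(code: str) -> str:
    """Chapter letter of an ICPC-2 code (``"R74"`` → ``"R"``)."""
    return validate_icpc(code)[0]


def is_symptom_code(code: str) -> bool:
    """True for symptom/complaint rubrics (rubric ≤ 29).

    Symptom diagnoses (cough R05, fever A03, ...) are flagged
    descriptively in the coverage tables; they never enter indicator
    denominators.
    """
    return int(validate_icpc(code)[1:]) <= SYMPTOM_RUBRIC_MAX


def is_antibiotic(code: str) -> bool:
    """True iff the ATC code falls under J01 (systemic antibacterials)."""
    return validate_atc(code).startswith(ANTIBACTERIAL_PREFIX)


def is_quinolone(code: str) -> bool:
    """True iff the ATC code falls under J01M (quinolone antibacterials)."""
    return validate_atc(code).startswith(QUINOLONE_PREFIX)


def atc_matches(code: str, prefixes: Iterable[str]) -> bool:
    """Prefix-semantics ATC membership: code matches any listed level."""
    return any(code.startswith(p) for p in prefixes)


@dataclass(frozen=True)
class IndicatorDefinition:
    """One disease-specific indicator: eligibility window, recommended
    antibiotics and acceptable ranges.

    ``min_age``/``max_age`` are inclusive bounds in completed years
    (``None`` = unbounded); ``sex`` restricts to ``"F"``/``"M"`` when
    set.  ``recommended`` holds ATC codes at any level, matched by
    prefix.  Ranges are ``(low, high)`` pairs in percent with ``None``
    for an unbounded side; ``proposed`` marks ranges not yet backed by
    consensus indicators.
    """

    icpc: str
    label: str
    min_age: float | None = None
    max_age: float | None = None
    sex: str | None = None
    recommended: tuple[str, ...] = ()
    range_a: tuple[float | None, float | None] = (None, None)
    range_b: tuple[float | None, float | None] = (None, None)
    range_c: tuple[float | None, float | None] = (None, None)
    proposed: bool = False

    def __post_init__(self) -> None:
        validate_icpc(self.icpc)
        if not self.recommended:
            raise ConfigError(f"{self.icpc}: recommended antibiotic set is empty")
        for atc in self.recommended:
            validate_atc(atc)
            if not atc.startswith(ANTIBACTERIAL_PREFIX):
                raise ConfigError(
                    f"{self.icpc}: recommended code {atc} is not a J01 antibacterial"
                )
        if self.min_age is not None and self.max_age is not None:
            if self.min_age > self.max_age:
                raise ConfigError(f"{self.icpc}: min_age > max_age")
        if self.sex not in (None, "F", "M"):
            raise ConfigError(f"{self.icpc}: sex restriction must be F, M or null")
        for name, rng in (("a", self.range_a), ("b", self.range_b), ("c", self.range_c)):
            for bound in rng:
                if bound is not None and not 0 <= bound <= 100:
                    raise ConfigError(f"{self.icpc}: range_{name} bound outside [0,100]")


def _parse_range(raw) -> tuple[float | None, float | None]:
    if raw is None:
        return (None, None)
    lo, hi = raw
    return (None if lo is None else float(lo), None if hi is None else float(hi))


def load_config(source) -> dict[str, IndicatorDefinition]:
    """Load an indicator configuration from a YAML/JSON mapping.

    *source* may be a path or an already-parsed mapping.  Returns an
    ordered ``{icpc: IndicatorDefinition}`` dict.
    """
    if isinstance(source, Mapping):
        raw = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    entries = raw["indicators"] if "indicators" in raw else raw
    config: dict[str, IndicatorDefinition] = {}
    for entry in entries:
        d = IndicatorDefinition(
            icpc=entry["icpc"],
            label=entry.get("label", entry["icpc"]),
            min_age=entry.get("min_age"),
            max_age=entry.get("max_age"),
            sex=entry.get("sex"),
            recommended=tuple(entry["recommended"]),
            range_a=_parse_range(entry.get("range_a")),
            range_b=_parse_range(entry.get("range_b")),
            range_c=_parse_range(entry.get("range_c")),
            proposed=bool(entry.get("proposed", False)),
        )
        config[d.icpc] = d
    return config


def default_config() -> dict[str, IndicatorDefinition]:
    """The shipped nine-indication configuration (seven consensus APQI
    indications plus the proposed erysipelas and teeth/gum entries)."""
    text = resources.files("apqi.data").joinpath("indicators.yaml").read_text("utf-8")
    return load_config(yaml.safe_load(text))


def is_recommended(
    code: str, indication: str, config: Mapping[str, IndicatorDefinition]
) -> bool:
    """True iff *code* matches the indication's recommended ATC set.

    Raises :class:`ConfigError` (listing the configured indications)
    when the indication is absent from *config*.
    """
    validate_atc(code)
    if indication not in config:
        raise ConfigError(
            f"indication {indication!r} not configured; available: "
            f"{sorted(config)}"
        )
    return atc_matches(code, config[indication].recommended)
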
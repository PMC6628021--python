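"""Published benchmark counts and worked-example fixtures.

The record-level data behind the two-year, five-cooperative audit that
motivates this package are not public; what is public are its summary
tables — antibiotic prescriptions per ICPC-2 chapter, per indicator
diagnosis, the pooled indicator percentages with their between-site
brackets, and the overall totals.  This module loads those counts from
``data/ooh_benchmark.yaml`` and can expand them into a synthetic set of
linked prescriptions that reproduces every printed count exactly, so the
coverage arithmetic can be exercised end to end.

The expansion is synthetic: residual chapter counts (prescriptions in a
chapter not linked to an indicator diagnosis) are attributed to a fixed
set of filler codes, each kept below the 3 % ranking threshold, with
symptom-coded fillers sized so the symptom share matches the published
3.8 %.  Chapter totals, indication totals, the missing-diagnosis count
and the grand total are exact.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .data_io import LinkedPrescription

__all__ = ["load_benchmark", "benchmark_links", "benchmark_labels"]


def load_benchmark() -> dict:
    """The shipped benchmark summary counts, as a nested dict."""
    text = resources.files("apqi.data").joinpath("ooh_benchmark.yaml").read_text("utf-8")
    return yaml.safe_load(text)


#: Labels for the ranked indication table.
_LABELS = {
    "R74": "Acute upper respiratory tract infection",
    "U71": "Acute cystitis",
    "R76": "Acute tonsillitis",
    "R78": "Acute bronchitis",
    "H71": "Acute otitis media",
    "S76": "Erysipelas",
    "D82": "Teeth/gum disease",
    "R75": "Acute sinusitis",
    "R81": "Pneumonia",
}


def benchmark_labels() -> dict[str, str]:
    return dict(_LABELS)


def _filler_counts(bm: dict) -> dict[str | None, int]:
    """Distribute residual chapter counts over filler codes (<3 % each).

    Residual per chapter = published chapter count minus the indicator
    diagnoses belonging to it.  Symptom-coded fillers (R05 cough, R21
    throat complaint, A03 fever) carry the published symptom share.
    """
    ch = bm["chapter_counts"]
    ind = bm["indication_counts"]
    total = bm["study"]["total_prescriptions"]
    resid_r = ch["R"] - sum(ind[c] for c in ("R74", "R76", "R78", "R75", "R81"))
    resid_u = ch["U"] - ind["U71"]
    resid_s = ch["S"] - ind["S76"]
    resid_h = ch["H"] - ind["H71"]
    resid_d = ch["D"] - ind["D82"]
    # symptom fillers: hit the published symptom prescription share exactly
    # after rounding to one decimal
    n_sym = round(bm["symptom_prescription_share"] / 100.0 * total)
    sym_r = min(resid_r, round(n_sym * 0.8))
    sym_a = n_sym - sym_r
    fillers: dict[str | None, int] = {}
    # respiratory residual: symptoms plus disease fillers split below 3 %
    fillers["R05"] = sym_r - sym_r // 2
    fillers["R21"] = sym_r // 2
    rest_r = resid_r - sym_r
    fillers["R77"] = rest_r - rest_r // 2
    fillers["R80"] = rest_r // 2
    fillers["U70"] = resid_u
    fillers["S70"] = resid_s // 3
    fillers["S84"] = resid_s // 3
    fillers["S88"] = resid_s - 2 * (resid_s // 3)
    fillers["H72"] = resid_h
    fillers["D87"] = resid_d
    # pooled small chapters (A, L, K, X, ...)
    fillers["A03"] = sym_a
    rest_other = ch["other"] - sym_a
    quarter = rest_other // 4
    fillers["A78"] = quarter
    fillers["L70"] = quarter
    fillers["K70"] = quarter
    fillers["X71"] = rest_other - 3 * quarter
    fillers[None] = ch["missing"]
    return {k: v for k, v in fillers.items() if v}


def benchmark_links(site_id: str = "pooled") -> list[LinkedPrescription]:
    """Expand the benchmark counts into per-prescription links.

    Every indication count, chapter count, the missing-diagnosis count
    and the grand total match the published table exactly; all
    prescriptions are represented by a generic J01 code since the
    coverage tables only use the diagnosis side.
    """
    bm = load_benchmark()
    counts: dict[str | None, int] = dict(bm["indication_counts"])
    for code, n in _filler_counts(bm).items():
        counts[code] = counts.get(code, 0) + n
    links: list[LinkedPrescription] = []
    i = 0
    for diag, n in counts.items():
        for _ in range(n):
            links.append(
                LinkedPrescription(
                    site_id=site_id,
                    encounter_id=f"B{i:06d}",
                    atc="J01CA04",
                    diagnosis=diag,
                )
            )
            i += 1
    assert len(links) == bm["study"]["total_prescriptions"]
    return links
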
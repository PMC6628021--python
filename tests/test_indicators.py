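"""The indicator engine: eligibility, a/b/c arithmetic, classification,
per-site brackets, and equivalence with a brute-force recount."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from apqi import (
    RangeClass,
    classify,
    compute_indicator,
    is_eligible,
    per_site_ranges,
)
from conftest import make_record


# ---------------------------------------------------------------------------
# independent oracle: plain nested loops, no shared helpers
def oracle_counts(records, definition, strict_age=False):
    n_el = n_ab = n_rec = n_quin = 0
    for r in records:
        if definition.icpc not in r.diagnoses:
            continue
        if definition.min_age is not None:
            if strict_age and not r.age_years > definition.min_age:
                continue
            if not strict_age and r.age_years < definition.min_age:
                continue
        if definition.max_age is not None and r.age_years > definition.max_age:
            continue
        if definition.sex is not None and r.sex != definition.sex:
            continue
        n_el += 1
        has_ab = has_rec = has_quin = False
        for p in r.prescriptions:
            if p.startswith("J01"):
                has_ab = True
                if p.startswith("J01M"):
                    has_quin = True
                for prefix in definition.recommended:
                    if p.startswith(prefix):
                        has_rec = True
        if has_ab:
            n_ab += 1
            if has_rec:
                n_rec += 1
            if has_quin:
                n_quin += 1
    return n_el, n_ab, n_rec, n_quin


def random_records(rng, n):
    diags = ["R76", "H71", "U71", "R78", "R05", "S76"]
    drugs = ["J01CE02", "J01CA04", "J01MA02", "J01XE01", "N02BE01", "J01CR02"]
    out = []
    for i in range(n):
        out.append(
            make_record(
                rng.sample(diags, rng.randint(0, 2)),
                rng.sample(drugs, rng.randint(0, 3)),
                age=rng.choice([0.5, 1, 2, 5, 17, 18, 30, 64, 65, 75, 76, 90]),
                sex=rng.choice("FMU"),
                site=rng.choice(["GPC1", "GPC2", "GPC3"]),
                encounter_id=f"E{i}",
            )
        )
    return out


class TestEligibility:
    def test_diagnosis_and_window_required(self, config):
        cyst = config["U71"]
        assert is_eligible(make_record(["U71"], age=30, sex="F"), cyst)
        assert not is_eligible(make_record(["U71"], age=30, sex="M"), cyst)
        assert not is_eligible(make_record(["R76"], age=30, sex="F"), cyst)

    def test_age_window_inclusive(self, config):
        bron = config["R78"]  # 18-75 years
        assert is_eligible(make_record(["R78"], age=18), bron)
        assert is_eligible(make_record(["R78"], age=75), bron)
        assert not is_eligible(make_record(["R78"], age=80), bron)
        assert not is_eligible(make_record(["R78"], age=17.9), bron)

    def test_strict_age_variant(self, config):
        oti = config["H71"]  # older than two years
        assert is_eligible(make_record(["H71"], age=2), oti)
        assert not is_eligible(make_record(["H71"], age=2), oti, strict_age=True)
        assert is_eligible(make_record(["H71"], age=2.1), oti, strict_age=True)


class TestComputeIndicator:
    def test_worked_tonsillitis_quartet(self, config, tonsillitis_quartet):
        res = compute_indicator(tonsillitis_quartet, config["R76"])
        assert (res.n_eligible, res.n_ab, res.n_recommended, res.n_quinolone) == (3, 2, 1, 0)
        assert res.a == 66.7 and res.b == 50.0 and res.c == 0.0
        assert res.class_a is RangeClass.ABOVE
        assert res.class_c is RangeClass.WITHIN

    def test_empty_records_undefined(self, config):
        res = compute_indicator([], config["R76"])
        assert res.n_eligible == 0 and res.a is None and res.b is None
        assert res.class_a is RangeClass.UNDEFINED

    def test_unconditional_variant_uses_eligible_denominator(self, config, tonsillitis_quartet):
        res = compute_indicator(tonsillitis_quartet, config["R76"], conditional=False)
        assert res.b == 33.3  # 1 recommended / 3 eligible
        assert res.c == 0.0

    def test_count_ordering_invariant(self, config):
        rng = random.Random(7)
        res = compute_indicator(random_records(rng, 200), config["H71"])
        assert 0 <= res.n_recommended <= res.n_ab <= res.n_eligible
        assert 0 <= res.n_quinolone <= res.n_ab

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, config, seed):
        """On any small record set the engine agrees exactly with an
        independent nested-loop recount, for every indication."""
        rng = random.Random(seed)
        records = random_records(rng, rng.randint(0, 50))
        for d in config.values():
            res = compute_indicator(records, d, by_site=False)
            assert (
                res.n_eligible,
                res.n_ab,
                res.n_recommended,
                res.n_quinolone,
            ) == oracle_counts(records, d)

    def test_monotonicity_of_a(self, config):
        """Adding a treated eligible encounter never lowers a; adding an
        untreated eligible encounter never raises it."""
        rng = random.Random(3)
        records = random_records(rng, 40)
        base = compute_indicator(records, config["R76"], by_site=False).a
        treated = records + [make_record(["R76"], ["J01CA04"], age=20, encounter_id="T")]
        untreated = records + [make_record(["R76"], [], age=20, encounter_id="U")]
        a_t = compute_indicator(treated, config["R76"], by_site=False).a
        a_u = compute_indicator(untreated, config["R76"], by_site=False).a
        if base is not None:
            assert a_t >= base >= a_u
        else:
            assert a_t == 100.0 and a_u == 0.0


class TestClassify:
    @pytest.mark.parametrize(
        "value,rng,expected",
        [
            (77, (None, 20), RangeClass.ABOVE),
            (1, (None, 5), RangeClass.WITHIN),
            (20, (None, 20), RangeClass.WITHIN),  # closed at stated bound
            (79.9, (80, 100), RangeClass.BELOW),
            (80, (80, 100), RangeClass.WITHIN),
            (None, (0, 20), RangeClass.UNDEFINED),
        ],
    )
    def test_examples(self, value, rng, expected):
        assert classify(value, rng) is expected

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0, 100),
        st.floats(0, 100),
        st.floats(0, 100),
    )
    def test_within_iff_inside(self, value, b1, b2):
        lo, hi = min(b1, b2), max(b1, b2)
        cls = classify(value, (lo, hi))
        assert cls is not RangeClass.UNDEFINED
        assert (cls is RangeClass.WITHIN) == (lo <= value <= hi)


class TestPerSite:
    def test_identical_sites_zero_width(self, config):
        recs = [
            make_record(["R76"], ["J01CE02"], age=20, site=s, encounter_id=f"{s}-1")
            for s in ("GPC1", "GPC2")
        ] + [
            make_record(["R76"], [], age=20, site=s, encounter_id=f"{s}-2")
            for s in ("GPC1", "GPC2")
        ]
        _, brackets, _ = per_site_ranges(recs, config["R76"])
        assert brackets["a"] == (50.0, 50.0)

    def test_hand_built_bracket_contains_pooled(self, config):
        recs = [
            make_record(["R76"], ["J01CA04"], age=20, site="GPC1", encounter_id="A1"),
            make_record(["R76"], [], age=20, site="GPC1", encounter_id="A2"),
            make_record(["R76"], ["J01CA04"], age=20, site="GPC2", encounter_id="B1"),
        ]
        res = compute_indicator(recs, config["R76"])
        assert res.brackets["a"] == (50.0, 100.0)
        assert 50.0 <= res.a <= 100.0
        assert res.per_site["GPC1"][0] == 50.0 and res.per_site["GPC2"][0] == 100.0

    def test_single_site_bracket_equals_pooled(self, config):
        recs = [make_record(["R76"], ["J01CA04"], age=20, encounter_id="A1")]
        res = compute_indicator(recs, config["R76"])
        assert res.brackets["a"] == (res.a, res.a)

    def test_site_without_eligible_excluded_and_listed(self, config):
        recs = [
            make_record(["R76"], ["J01CA04"], age=20, site="GPC1", encounter_id="A1"),
            make_record(["H71"], [], age=20, site="GPC2", encounter_id="B1"),
        ]
        per_site, brackets, empty = per_site_ranges(recs, config["R76"])
        assert empty == ["GPC2"]
        assert brackets["a"] == (100.0, 100.0)
        assert per_site["GPC2"] == (None, None, None)
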
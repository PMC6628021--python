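"""The synthetic encounter generator: reproducibility, calibration and
parameter recovery."""

import dataclasses

import pytest

from apqi import (
    compute_indicator,
    default_config,
    default_scenario,
    generate,
    link_prescriptions,
    read_encounters,
    write_encounters,
)
from apqi.synthetic import (
    MISSING_KEY,
    OTHER_KEY,
    SYMPTOM_KEY,
    DiagnosisProfile,
    scenario_from_file,
)

INDICATIONS = ("H71", "R74", "R75", "R76", "R78", "R81", "U71", "S76", "D82")


@pytest.fixture(scope="module")
def scenario():
    return default_scenario()


def single_diagnosis_scenario(scenario, icpc, **profile_overrides):
    """Focus the whole encounter stream on one diagnosis."""
    profile = scenario.profiles[icpc]
    if profile_overrides:
        profile = dataclasses.replace(profile, **profile_overrides)
    return dataclasses.replace(
        scenario,
        diagnosis_mix={icpc: 1.0},
        profiles={icpc: profile},
    )


class TestScenario:
    def test_default_probability_vectors_valid(self, scenario):
        scenario.validate()
        assert abs(sum(scenario.diagnosis_mix.values()) - 1.0) < 1e-9
        assert abs(sum(scenario.site_weights) - 1.0) < 1e-9

    def test_default_has_nine_indicator_diagnoses(self, scenario):
        assert set(INDICATIONS) <= set(scenario.diagnosis_mix)
        assert {MISSING_KEY, SYMPTOM_KEY, OTHER_KEY} <= set(scenario.diagnosis_mix)

    def test_profiles_match_configured_benchmarks(self, scenario):
        for icpc in INDICATIONS:
            p = scenario.profiles[icpc]
            assert 0 < p.p < 1 and p.r + p.q <= 1

    def test_invalid_scenario_rejected_before_sampling(self, scenario):
        bad = dataclasses.replace(scenario, site_weights=(0.5, 0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="site_weights"):
            generate(bad, n_encounters=10)


class TestGenerate:
    def test_n_zero_empty(self, scenario):
        assert generate(scenario, n_encounters=0) == []

    def test_same_seed_byte_identical(self, scenario, tmp_path):
        a, b = (generate(scenario, n_encounters=400, seed=5) for _ in range(2))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_encounters(a, pa)
        write_encounters(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self, scenario):
        assert generate(scenario, 400, seed=1) != generate(scenario, 400, seed=2)

    def test_prefix_stable_under_larger_n(self, scenario):
        """Requesting more encounters never reshuffles earlier records."""
        small = generate(scenario, n_encounters=150, seed=9)
        large = generate(scenario, n_encounters=600, seed=9)
        assert large[:150] == small

    def test_degenerate_certain_prescribing(self, scenario, config):
        sc = single_diagnosis_scenario(scenario, "R76", p=1.0, r=1.0, q=0.0)
        records = generate(sc, n_encounters=300, seed=2)
        assert all(r.diagnoses == ("R76",) for r in records)
        res = compute_indicator(records, config["R76"], by_site=False)
        assert res.a == 100.0 and res.b == 100.0 and res.c == 0.0

    def test_round_trip_through_files(self, scenario, config, tmp_path):
        """Write, re-read, re-link: indicator results identical to the
        in-memory computation."""
        records = generate(scenario, n_encounters=2000, seed=4)
        path = tmp_path / "synthetic.csv"
        write_encounters(records, path)
        reread, report = read_encounters(path)
        assert report.n_excluded == 0
        assert reread == records
        links_mem, rep_mem = link_prescriptions(records)
        links_io, rep_io = link_prescriptions(reread)
        assert links_mem == links_io and rep_mem == rep_io
        for icpc in ("R76", "U71"):
            assert compute_indicator(reread, config[icpc]) == compute_indicator(
                records, config[icpc]
            )

    def test_eligibility_violations_are_generated(self, scenario, config):
        """Ages and sexes straddle the eligibility boundaries so filters
        are exercised on both sides."""
        records = generate(scenario, n_encounters=30000, seed=6)
        u71 = [r for r in records if "U71" in r.diagnoses]
        assert any(r.sex == "M" for r in u71)
        h71 = [r for r in records if "H71" in r.diagnoses]
        assert any(r.age_years < 2 for r in h71)
        assert any(r.age_years >= 2 for r in h71)


class TestCalibration:
    def test_diagnosis_mix_recovered(self, scenario):
        """Mean absolute deviation between realized and configured
        diagnosis shares stays below half a percentage point over
        ten seeds at n=50,000."""
        n = 50_000
        keys = list(scenario.diagnosis_mix)
        deviations = []
        for seed in range(10):
            records = generate(scenario, n_encounters=n, seed=seed)
            counts = dict.fromkeys(keys, 0)
            for r in records:
                if not r.diagnoses:
                    counts[MISSING_KEY] += 1
                elif r.diagnoses[0] in counts:
                    counts[r.diagnoses[0]] += 1
                elif r.diagnoses[0] in scenario.symptom_pool:
                    counts[SYMPTOM_KEY] += 1
                else:
                    counts[OTHER_KEY] += 1
            for k in keys:
                deviations.append(abs(counts[k] / n - scenario.diagnosis_mix[k]))
        mad = 100 * sum(deviations) / len(deviations)
        assert mad < 0.5

    @pytest.mark.parametrize("icpc", INDICATIONS)
    def test_parameter_recovery_per_indication(self, scenario, config, icpc):
        """Generating ~50,000 encounters of one diagnosis recovers the
        scenario's p/r/q as indicator a/b/c within 1.5 points
        (five binomial standard errors)."""
        sc = single_diagnosis_scenario(scenario, icpc)
        records = generate(sc, n_encounters=50_000, seed=100)
        res = compute_indicator(records, config[icpc], by_site=False)
        prof = sc.profiles[icpc]
        assert abs(res.a - 100 * prof.p) < 1.5
        assert abs(res.b - 100 * prof.r) < 1.5
        assert abs(res.c - 100 * prof.q) < 1.5

    def test_pooled_value_sits_inside_site_bracket(self, scenario, config):
        records = generate(scenario, n_encounters=40_000, seed=12)
        res = compute_indicator(records, config["R76"])
        lo, hi = res.brackets["a"]
        assert lo <= res.a <= hi
        assert hi - lo > 0  # heterogeneous sites


class TestScenarioFile:
    def test_override_profile_from_file(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(
            "n_encounters: 50\n"
            "seed: 3\n"
            "profiles:\n"
            "  R76: {p: 1.0, r: 1.0, recommended_atc: J01CE02}\n"
        )
        sc = scenario_from_file(path)
        assert sc.n_encounters == 50 and sc.seed == 3
        assert sc.profiles["R76"] == DiagnosisProfile(
            p=1.0, r=1.0, recommended_atc="J01CE02"
        )
        generate(sc)  # validates and samples
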
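# apqi — antibiotic prescribing quality indicators for out-of-hours primary care

Out-of-hours (OOH) general-practice cooperatives see a heavy load of
infections, most of them self-limiting, and antibiotic over-prescribing in
this setting is a well-documented driver of antimicrobial resistance.  This
package implements the disease-specific **antibiotic prescribing quality
indicators (APQI)** used to audit that prescribing from routinely collected
encounter data (ICPC-2 diagnoses linked to ATC prescriptions), for
epidemiologists and quality-of-care teams who run audit-and-feedback
programmes on OOH cooperatives.

For each indication *d* with eligibility window *E_d* (age range, sex),
three percentages are computed over the encounters carrying diagnosis *d*
and satisfying *E_d*:

* **a** = 100 · (eligible encounters with ≥1 J01 prescription) / (eligible encounters)
* **b** = 100 · (treated encounters with ≥1 guideline-recommended antibiotic) / (treated encounters)
* **c** = 100 · (treated encounters with ≥1 quinolone, J01M) / (treated encounters)

Each value is classified against an acceptable range (e.g. a < 20 % for
upper respiratory infection, b > 80 %, c < 5 %) and reported with the
min–max bracket across sites.  A complementary appraisal transposes the
**DU90%** concept from drugs to indications: how many diagnoses account for
90 % of all antibiotic prescriptions, and what share the indicator
diagnoses cover.  Because the clinical databases behind such audits are not
redistributable, a seed-reproducible synthetic encounter generator —
calibrated to a published two-year, five-cooperative audit — makes the
whole pipeline runnable and testable out of the box.

## Worked example

```python
from apqi import (default_scenario, generate, compute_all,
                  link_prescriptions, coverage_of_set, APQI7)

records = generate(default_scenario(), n_encounters=50_000, seed=42)
results = compute_all(records)
r76 = next(r for r in results if r.icpc == "R76")
print(r76.icpc, r76.a, r76.class_a.value, r76.brackets["a"])

links, _ = link_prescriptions(records)
cov = coverage_of_set(links, APQI7, n_encounters=len(records))
print(cov.covered_share, cov.n_diagnoses_for_90pct)
```

prints

```
R76 77.7 ABOVE (69.3, 87.0)
56.9 20
```

meaning: 77.7 % of eligible tonsillitis patients received an antibiotic —
far above the <20 % acceptable range — with individual sites ranging from
69.3 % to 87.0 %; the seven consensus indicator diagnoses cover only
56.9 % of all antibiotic prescriptions, and 20 diagnoses would be needed
to reach the 90 % mark of a DU90%-style profile.

The same pipeline is available as a thin CLI
(`apqi simulate | compute | describe | report`), and `examples/` contains
one narrative script per capability — generation, indicators, coverage
appraisal, feedback report — each printing its numbers with a line on what
they mean.  Real data are read with `read_encounters()` from delimited
text (see `docs/data_dictionary.md`); indicator definitions, including the
recommended-antibiotic sets and acceptable ranges, are editable YAML
(`src/apqi/data/indicators.yaml`).

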
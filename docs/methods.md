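# Methods

## The indicator model

The unit of analysis is the **encounter** (one OOH consultation).  The data
carry no stable patient identifier across sites, so encounters stand in for
patients throughout; for OOH care, where repeat visits within an episode are
rare, this is the standard proxy and it matches how the benchmark tables the
defaults are calibrated to were constructed.

For an indication *d* (an ICPC-2 disease code) with eligibility window
*E_d*, let *N* be the eligible encounters carrying *d*, *T ⊆ N* those with
at least one systemic antibacterial (ATC prefix `J01`), *R ⊆ T* those with
at least one recommended antibiotic and *Q ⊆ T* those with at least one
quinolone (`J01M`).  Then

    a = 100·|T|/|N|,   b = 100·|R|/|T|,   c = 100·|Q|/|T|.

`b` and `c` are **conditional on treatment**.  The phrase "treated patients
receiving the recommended antibiotic" is ambiguous between denominators
|N| and |T|, but the acceptable ranges (b > 80 %) are only coherent on |T|:
an indication with a = 30 % could never reach b > 80 % on the unconditional
denominator.  `conditional=False` exposes the other reading.

An encounter can belong to both *R* and *Q* (two prescriptions in one
consultation).  Zero denominators yield `None` values classified
`UNDEFINED`, never exceptions.

### Eligibility and age boundaries

Eligibility windows are phrased as "older than two years", "between 18 and
75 years".  The package reads these as **inclusive bounds on completed
years**: `min_age=2` admits age 2.0, `18–75` admits both endpoints.  The
strict reading (> 2) is available via `strict_age=True`.  Sex restrictions
(cystitis: female) exclude non-matching and unknown (`U`) sexes.

### Rounding and classification

Percentages are computed at full precision, classified against their
acceptable range **unrounded**, then stored to one decimal; display
renderers round to integers.  This avoids boundary artifacts where a value
of 19.96 would classify differently before and after rounding.  Ranges are
closed at their stated bounds: a = 20 is `WITHIN` a `<20 %`-style range
expressed as [0, 20].

Integer shares quoted from count tables (chapter shares, ranked-indication
shares) are rounded directly from the exact count ratio, not from the
stored one-decimal value — double rounding would turn 13.48 % → 13.5 → 14.

### Per-site variation

Brackets are the min–max of the per-site values over sites with defined
values; sites with zero eligible encounters are excluded from brackets and
listed separately.  The pooled value need not sit inside the bracket in
degenerate cases (a site with defined a but zero treated encounters has
undefined b), which is why the property tests only assert containment on
non-degenerate data.

## Linking prescriptions to diagnoses

All tables run off one flattening: one row per prescription, linked to the
diagnosis registered in the same consultation (`None` when no diagnosis was
registered).  When a consultation carries several diagnoses each
prescription is linked to the **first-listed** diagnosis and the encounter
is flagged; this preserves the identity links = prescriptions that every
conservation check relies on.  `link_all=True` duplicates links across
diagnoses for sensitivity analysis (and deliberately breaks that identity).

## Coverage appraisal (DU90% over indications)

The drug-utilization-90 % idea — how many items account for 90 % of use —
is applied to diagnoses: diagnoses are ranked by antibiotic prescription
count (ties broken by ICPC code for determinism) and the report states the
minimal number whose cumulative share reaches 90 %, or `None` when
unreachable.  The denominator of every share **includes** the
missing-diagnosis prescriptions, so missing diagnoses count against
coverage (with >10 % missing, 90 % is unreachable by construction); the
missing pool itself is never counted as a "diagnosis" in the ranking.
Symptom codes (rubrics ≤ 29: fever, cough, ...) are flagged descriptively
in the coverage report but never enter indicator denominators.

## Indicator configuration

Recommended-antibiotic sets are data, not code.  Published indicator tables
state *that* a recommended set exists per indication but not its ATC
members, so the shipped defaults follow Belgian first-choice guidance:
narrow-spectrum penicillin (`J01CE`) for tonsillitis and upper RTI,
amoxicillin (`J01CA04`) for otitis media, sinusitis, bronchitis, pneumonia
and teeth/gum disease, nitrofurantoin derivatives (`J01XE`) for cystitis,
flucloxacillin-class (`J01CF`) for erysipelas.  Membership uses ATC
**prefix matching** so sets can be written at any level; configs do not
distinguish first-line-only from any-acceptable — encode whichever reading
local guidance implies by listing more or fewer prefixes.  The acceptable
ranges default to a < 20 % (otitis media, upper RTI, sinusitis,
tonsillitis), a < 30 % (bronchitis), a > 80 % (pneumonia, cystitis),
b > 80 % and c < 5 % everywhere, plus proposed ranges for the two
extension indications (erysipelas a > 80 %, teeth/gum a < 30 %), flagged
`proposed: true`.  Tests assert the mechanics of these defaults, not their
clinical truth.

## The synthetic generator

Each encounter draws, in order: site, diagnosis category, age stratum and
age within it, sex, antibiotic yes/no, drug class, and (for pooled
categories) the concrete code.  Categories are the nine indicator
diagnoses, a symptom pool, a missing-diagnosis state and an "other
diagnoses" pool.

**Calibration.**  The default scenario inverts the published summary
tables: the encounter-level frequency of diagnosis *d* is its published
prescription count divided by its published prescribing percentage (count/
(a_d·111,600)), so the *generated prescriptions* reproduce the published
diagnosis mix while the indicator engine recovers a_d.  Per-diagnosis
recommended and quinolone fractions equal the published b_d and c_d.  Six
percent of encounters carry no diagnosis and four percent a symptom code,
with their prescribing probabilities set so missing and symptom
prescriptions match their published shares (6 % and 3.8 % of
prescriptions); the residual "other" pool absorbs the remaining mass at
the rate that reproduces the overall 23.7 prescriptions per 100
encounters.

**Site heterogeneity.**  Five sites with population-proportional weights
receive log-odds offsets (−0.45 … +0.45) on every prescribing probability.
The offsets are recentred per diagnosis by bisection so the weighted
pooled probability equals the scenario parameter *exactly* — heterogeneity
widens the between-site brackets (roughly spanning the published ones)
without biasing pooled recovery.  Offsets at p ∈ {0, 1} are skipped
(degenerate scenarios stay degenerate).

**Determinism.**  All randomness comes from a counter-based Philox stream
consuming a fixed eight uniforms per encounter, reshaped row-wise: output
is byte-identical across runs for a given seed, and the first *k* records
are identical for any requested size ≥ *k* (subsetting never reshuffles).
Dates are assigned deterministically by cycling the two-year window; drug
classes map to one representative ATC code per class per indication (a
full drug-mix model would add nothing the indicator paths can see).

**What it does not emulate.**  No seasonality, no repeat visits or
patient-level correlation, no delayed prescriptions, no multi-diagnosis or
multi-prescription encounters, no dispensing/adherence.  Passing tests
therefore show the *pipeline arithmetic* is right under the assumed
structure; they say nothing about registration quality, diagnosis shifting
or other real-data pathologies, which must be assessed on real data via
the validation report that `read_encounters` emits.

## Problem sizes and tolerances

Parameter-recovery tests use 50,000 single-diagnosis encounters per
indication (tolerance 1.5 points ≈ 5 binomial standard errors) and the
end-to-end recovery check uses 100,000 mixed encounters against a 2-point
band; the reproduction script uses 200,000, where the binomial standard
error of the recovered percentages is ≈ 0.6–0.7 points.  Calibration of
the realized diagnosis mix is checked as a mean absolute deviation
< 0.5 points over ten seeds at 50,000 encounters.  These sizes keep the
whole suite in the tens of seconds while leaving comfortable stochastic
margins.

## Known limitations

* Recommended sets encode ATC membership only — no dosing, duration or
  second-line logic.
* Encounter ≠ patient; repeated visits by one patient inflate
  denominators symmetrically.
* Home visits are assumed pre-filtered by the caller; the reader does not
  special-case them.
* The report schema validator covers the structural subset the shipped
  schema uses (type/required/properties/items/$ref), not full JSON
  Schema.
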
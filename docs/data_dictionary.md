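# Encounter file data dictionary

Delimited text (comma or tab; auto-detected from the header or forced via
`read_encounters(path, delimiter=...)`), UTF-8, one row per consultation.

| column        | type            | constraints and meaning                                        |
|---------------|-----------------|----------------------------------------------------------------|
| `site_id`     | string          | identifier of the OOH cooperative                              |
| `encounter_id`| string          | unique within a site                                           |
| `date`        | ISO-8601 date   | consultation date                                              |
| `age_years`   | number          | completed years, 0–120; fractional allowed for infants (0.5)   |
| `sex`         | `F`/`M`/`U`     | `U` = unknown; never matches a sex restriction                 |
| `icpc`        | list            | semicolon-separated ICPC-2 codes; empty = diagnosis missing    |
| `atc`         | list            | semicolon-separated ATC codes (any level); empty = none        |

Example:

```csv
site_id,encounter_id,date,age_years,sex,icpc,atc
GPC1,E0001,2017-01-15,30,F,R76,J01CE02
GPC1,E0002,2017-01-15,5,M,R76;H71,J01CA04;N02BE01
GPC1,E0003,2017-01-16,0.5,F,,
```

Rows failing validation (malformed code, out-of-range age, bad date,
duplicate id) are excluded and itemised in the `ValidationReport`; a
missing column aborts with a `SchemaError`.  Home visits must be filtered
out before writing the file — only consultations at the cooperative
belong in the analysis.
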
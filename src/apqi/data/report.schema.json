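{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Antibiotic prescribing quality feedback report",
  "type": "object",
  "required": ["schema_version", "indicators", "coverage", "chapters", "ranking"],
  "properties": {
    "schema_version": {"type": "integer"},
    "indicators": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["icpc", "label", "n_eligible", "n_ab", "n_recommended", "n_quinolone", "a", "b", "c", "per_site"],
        "properties": {
          "icpc": {"type": "string"},
          "label": {"type": "string"},
          "n_eligible": {"type": "integer"},
          "n_ab": {"type": "integer"},
          "n_recommended": {"type": "integer"},
          "n_quinolone": {"type": "integer"},
          "a": {"$ref": "#/$defs/value"},
          "b": {"$ref": "#/$defs/value"},
          "c": {"$ref": "#/$defs/value"},
          "per_site": {"type": "object"}
        }
      }
    },
    "coverage": {
      "type": "object",
      "required": ["total_prescriptions", "covered_count", "covered_share", "n_diagnoses_for_90pct", "symptom_share"],
      "properties": {
        "total_prescriptions": {"type": "integer"},
        "covered_count": {"type": "integer"},
        "covered_share": {"type": "number"},
        "n_diagnoses_for_90pct": {"type": ["integer", "null"]},
        "symptom_share": {"type": "number"},
        "prescribing_rate": {"type": ["number", "null"]}
      }
    },
    "chapters": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["chapter", "count", "share"],
        "properties": {
          "chapter": {"type": "string"},
          "count": {"type": "integer"},
          "share": {"type": "number"}
        }
      }
    },
    "ranking": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code", "label", "n_prescriptions", "share", "cumulative_share", "in_apqi_set"],
        "properties": {
          "code": {"type": "string"},
          "label": {"type": "string"},
          "n_prescriptions": {"type": "integer"},
          "share": {"type": "number"},
          "cumulative_share": {"type": "number"},
          "in_apqi_set": {"type": "boolean"}
        }
      }
    }
  },
  "$defs": {
    "value": {
      "type": "object",
      "required": ["value", "class", "bracket"],
      "properties": {
        "value": {"type": ["number", "null"]},
        "class": {"type": "string"},
        "bracket": {"type": ["array", "null"]}
      }
    }
  }
}
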
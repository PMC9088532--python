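{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "crowdscreen performance report",
  "type": "object",
  "required": ["counts", "sensitivity_pct", "specificity_pct", "consensus_pct", "missed_record_ids"],
  "properties": {
    "counts": {
      "type": "object",
      "required": ["tp", "tn", "fp", "fn", "total"],
      "properties": {
        "tp": {"type": "integer"},
        "tn": {"type": "integer"},
        "fp": {"type": "integer"},
        "fn": {"type": "integer"},
        "total": {"type": "integer"}
      }
    },
    "sensitivity_pct": {"type": "number"},
    "specificity_pct": {"type": "number"},
    "consensus_pct": {"type": "number"},
    "included_consensus_pct": {"type": ["number", "null"]},
    "title_only_consensus_pct": {"type": ["number", "null"]},
    "missed_record_ids": {"type": "array", "items": {"type": "string"}}
  }
}
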
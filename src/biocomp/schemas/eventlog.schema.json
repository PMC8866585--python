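{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "biocomp event log record",
  "type": "object",
  "required": ["time", "source", "kind", "payload"],
  "properties": {
    "time": {"type": "number"},
    "source": {"type": "string", "enum": ["heart", "flytrap", "rule"]},
    "kind": {"type": "string"},
    "payload": {"type": "object"}
  }
}
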
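{
  "type": "object",
  "required": ["version", "seed", "effective_params", "stages"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "effective_params": {"type": "object"},
    "stages": {
      "type": "object",
      "required": ["census", "superposition", "sasa", "cysteines",
                   "interfaces", "pocket", "sec", "trajectory",
                   "activity", "sequence"],
      "properties": {
        "census": {"type": "object"},
        "superposition": {"type": "object"},
        "sasa": {"type": "object"},
        "cysteines": {"type": "object"},
        "interfaces": {"type": "object"},
        "pocket": {"type": "object"},
        "sec": {"type": "object"},
        "trajectory": {"type": "object"},
        "activity": {"type": "object"},
        "sequence": {"type": "object"}
      }
    }
  }
}
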
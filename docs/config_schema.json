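{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cgsynapse simulation configuration",
  "description": "Flat key/value document mirroring SimulationConfig; any subset of keys may be given as overrides (YAML or JSON). Units: nm, ns, kT.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "box_x": {"type": "number", "exclusiveMinimum": 0, "default": 500.0},
    "box_y": {"type": "number", "exclusiveMinimum": 0, "default": 500.0},
    "gap": {"type": "number", "exclusiveMinimum": 0, "default": 20.0},
    "dt": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
    "cutoff": {"type": "number", "exclusiveMinimum": 0, "default": 0.5},
    "D_mono_t": {"type": "number", "minimum": 0, "default": 0.01},
    "D_mono_r": {"type": "number", "minimum": 0, "default": 1.0},
    "D_cplx_t": {"type": "number", "minimum": 0, "default": 0.005},
    "D_cplx_r": {"type": "number", "minimum": 0, "default": 0.28},
    "copy_numbers": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "CTLA4_DIMER": {"type": "integer", "minimum": 0},
        "B7": {"type": "integer", "minimum": 0},
        "PD1": {"type": "integer", "minimum": 0},
        "PDL1": {"type": "integer", "minimum": 0}
      }
    },
    "affinities": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "trans_ctla4_b7": {"type": "number", "maximum": 0},
        "trans_pd1_pdl1": {"type": "number", "maximum": 0},
        "dimer_b7": {"type": "number", "maximum": 0},
        "cis_b7_pdl1": {"type": "number", "maximum": 0}
      }
    },
    "p_on": {"type": "number", "minimum": 0, "maximum": 1, "default": 1.0},
    "n_steps": {"type": "integer", "minimum": 0, "default": 10000000},
    "record_stride": {"type": "integer", "minimum": 1, "default": 10000},
    "seed": {"type": "integer", "default": 0},
    "excluded_volume": {"type": "boolean", "default": false},
    "disabled_rules": {
      "type": "array",
      "items": {
        "enum": ["trans_ctla4_b7", "trans_pd1_pdl1", "dimer_b7", "cis_b7_pdl1"]
      }
    }
  }
}
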
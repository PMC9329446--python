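{
  "type": "object",
  "required": ["config", "result"],
  "properties": {
    "config": {
      "type": "object",
      "required": ["alpha", "n_perm", "seed"],
      "properties": {
        "alpha": {"type": "number"},
        "n_perm": {"type": "integer"},
        "seed": {"type": "integer"}
      }
    },
    "result": {
      "type": "object",
      "required": ["roles", "mode", "totals", "grand_total", "explained_sum", "residual_sum", "regions", "varparts"],
      "properties": {
        "roles": {"type": "array", "items": {"type": "string"}},
        "mode": {"type": "string", "enum": ["cumulative", "average"]},
        "totals": {"type": "object"},
        "grand_total": {"type": "number"},
        "explained_sum": {"type": "number"},
        "residual_sum": {"type": "number"},
        "regions": {"type": "object"},
        "varparts": {"type": "object"}
      }
    },
    "selected_axes": {"type": "object"},
    "explained_percent": {"type": "number"},
    "residual_percent": {"type": "number"}
  }
}
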
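{
  "nominal": {
    "decreased_water": 0.0,
    "farm_closures_widespread": 0.0,
    "season_yield_collapse": 0.0
  },
  "t0_label": "drought period start",
  "time_unit": "months"
}
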
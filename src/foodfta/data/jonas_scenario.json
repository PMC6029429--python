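{
  "nominal": {
    "roads_are_obstructed": 0.0,
    "transit_service_suspended": 1.0
  },
  "t0_label": "storm end",
  "time_unit": "hours"
}
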
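{
  "graph": "radius",
  "rad_cutoff": 300,
  "cost_ssc": 1.0,
  "alpha": 0.7,
  "method": "leiden",
  "refine": false
}
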
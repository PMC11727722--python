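{
  "graph": "radius",
  "rad_cutoff": 400,
  "cost_ssc": 0.1,
  "alpha": 0.0,
  "method": "gmm",
  "refine": false
}
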
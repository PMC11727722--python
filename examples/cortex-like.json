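{
  "graph": "radius",
  "rad_cutoff": 150,
  "cost_ssc": 0.1,
  "alpha": 0.0,
  "method": "louvain",
  "refine": true,
  "r_refine": 50
}
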
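{
  "graph": "knn",
  "knn_k": 6,
  "cost_ssc": 0.1,
  "alpha": 0.0,
  "method": "louvain",
  "n_clusters": 4,
  "hvg_n": 100,
  "refine": true,
  "r_refine": 1.5
}
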
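[
  {
    "model":"k_sorted",
    "r":0.2,
    "n_reps":3,
    "f_c_mean":0.8788888889,
    "f_c_sem":0.0265506737,
    "n_clusters_mean":19.0,
    "n_clusters_sem":3.5118845843,
    "n_clusters_norm":null
  }
]
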
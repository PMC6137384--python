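"""Extract Pearson functional-connectivity features from ROI time series.

Simulates a small two-group cohort of region-averaged time series and
turns each subject into a flat vector of pairwise correlations (one value
per region pair, upper-triangle order).
"""

import numpy as np

import rnncluster as rnc

cfg = rnc.SyntheticConfig(R=10, T=120, n_group_pos=6, n_group_neg=5,
                          planted_edges=4, delta=0.4, seed=1)
atlas = rnc.synthetic_atlas(cfg.R)
cohort = rnc.simulate_cohort(cfg)
ds = rnc.build_feature_matrix(cohort, atlas)

print(f"{ds.n_subjects} subjects x {ds.n_features} edge features "
      f"(= {cfg.R}*{cfg.R - 1}/2 region pairs)")
planted = rnc.planted_edge_indices(cfg)
hc = ds.features[ds.labels == 1][:, planted].mean()
ad = ds.features[ds.labels == -1][:, planted].mean()
print(f"mean FC on planted edges: controls {hc:.3f}, patients {ad:.3f}")
print("-> the patient group's correlation is elevated by ~delta on the "
      "planted region pairs; all other edges share the background level "
      f"{cfg.base_r}.")
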
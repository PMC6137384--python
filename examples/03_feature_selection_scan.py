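"""Frequency-based feature selection and the feature-count scan.

Learners above the accuracy threshold are 'significant'; features are
ranked by how many significant learners drew them. Candidate feature-set
sizes are then re-screened by rebuilding ensembles restricted to the top
of the ranking.
"""

import numpy as np

import rnncluster as rnc

cfg = rnc.SyntheticConfig(R=20, n_group_pos=20, n_group_neg=16,
                          planted_edges=8, delta=0.5, seed=3)
D = rnc.simulate_feature_matrix(cfg)
train, test = rnc.split_dataset(D, 0.8, seed=3)
cc = rnc.ClusterConfig(k=80, n_samples=22, m_features=20, seed=3,
                       learner_kind="logistic")
cluster = rnc.evaluate_learners(rnc.build_cluster(train, cc), test)

sig = rnc.select_significant_learners(cluster, threshold=0.6)
ranking = rnc.feature_frequency(sig, D.n_features)
print(f"{len(sig)} of {cc.k} learners exceed accuracy 0.6")
print(f"count conservation: {ranking.counts.sum()} = {len(sig)} x {cc.m_features}")

scan = rnc.scan_feature_counts(train, test, ranking, (24, 32, 40, 48), cc)
for c, a in zip(scan.candidate_counts, scan.accuracy_per_count):
    print(f"  top-{c} feature pool -> ensemble accuracy {a:.3f}")
print(f"optimal feature count: {scan.optimal_count}")

planted = set(rnc.planted_edge_indices(cfg).tolist())
top = set(rnc.top_features(ranking, scan.optimal_count).tolist())
print(f"planted edges inside the selected set: {len(planted & top)}/{len(planted)}")
print("-> features that keep re-appearing in accurate learners are the "
      "discriminative ones; the scan picks how many to keep.")
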
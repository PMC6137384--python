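"""Build a random neural network cluster and compare it to its members.

Each of the k base classifiers sees a random subject subset and a random
feature subset; a test subject's label is the majority vote. The ensemble
is typically more accurate and more stable than its average member.
"""

import numpy as np

import rnncluster as rnc

cfg = rnc.SyntheticConfig(R=20, n_group_pos=20, n_group_neg=16,
                          planted_edges=8, delta=0.4, seed=2)
D = rnc.simulate_feature_matrix(cfg)
train, test = rnc.split_dataset(D, train_fraction=0.8, seed=2)

cc = rnc.ClusterConfig(k=60, n_samples=22, m_features=30, seed=2)
cluster = rnc.build_cluster(train, cc)
rnc.evaluate_learners(cluster, test)

acc = rnc.cluster_accuracy(cluster, test)
single = cluster.accuracies()
print(f"ensemble accuracy (majority vote over {cc.k} learners): {acc:.3f}")
print(f"single-learner accuracy: mean {single.mean():.3f}, "
      f"sd {single.std(ddof=1):.3f}, range [{single.min():.2f}, {single.max():.2f}]")
print("-> voting averages away the variance of individual learners, so the "
      "ensemble beats the typical member.")
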
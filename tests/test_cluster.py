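import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rnncluster as rnc
from rnncluster.cluster import (
    UnevaluatedClusterError,
    learner_accuracy_summary,
    out_of_bag_sets,
)

from conftest import stub_cluster


def make_dataset(n, n_features=6, seed=0, informative=None, shift=2.0):
    rng = np.random.default_rng(seed)
    y = np.where(np.arange(n) % 2 == 0, 1, -1)
    X = rng.normal(size=(n, n_features))
    if informative is not None:
        X[:, informative] += shift * y
    return rnc.LabeledDataset(X, y, tuple(f"s{i}" for i in range(n)))


# ------------------------------------------------------------------ split


@pytest.mark.parametrize("n, frac, sizes", [(61, 0.8, (48, 13)), (10, 0.8, (8, 2)), (7, 0.8, (5, 2))])
def test_split_sizes_follow_floor_rule(n, frac, sizes):
    train, test = rnc.split_dataset(make_dataset(n), frac, seed=0)
    assert (train.n_subjects, test.n_subjects) == sizes


def test_split_is_a_disjoint_cover_with_both_classes_in_train():
    D = make_dataset(23)
    train, test = rnc.split_dataset(D, 0.8, seed=5)
    ids = set(train.subject_ids) | set(test.subject_ids)
    assert ids == set(D.subject_ids)
    assert not set(train.subject_ids) & set(test.subject_ids)
    assert set(np.unique(train.labels)) == {-1, 1}


def test_split_deterministic_given_seed():
    D = make_dataset(30)
    a = rnc.split_dataset(D, 0.8, seed=9)
    b = rnc.split_dataset(D, 0.8, seed=9)
    assert a[0].subject_ids == b[0].subject_ids
    assert a[1].subject_ids == b[1].subject_ids


# ------------------------------------------------------------------ draws


def test_exhaustive_subject_draw_returns_all_rows():
    D = make_dataset(8)
    rng = np.random.default_rng(0)
    rows, feats = rnc.draw_subset(D, 8, 3, np.arange(6), rng)
    assert np.array_equal(rows, np.arange(8))
    assert np.unique(feats).size == 3


def test_feature_draw_unique_and_within_pool():
    D = make_dataset(10, n_features=4005)
    rng = np.random.default_rng(1)
    pool = np.arange(4005)
    _, feats = rnc.draw_subset(D, 5, 120, pool, rng)
    assert feats.size == 120
    assert np.unique(feats).size == 120
    assert feats.min() >= 0 and feats.max() < 4005


def test_draw_rejects_oversized_requests():
    D = make_dataset(4)
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        rnc.draw_subset(D, 5, 1, np.arange(6), rng)
    with pytest.raises(ValueError):
        rnc.draw_subset(D, 2, 7, np.arange(6), rng)


# ------------------------------------------------------------------ learners


def test_separable_toy_set_is_learned_perfectly(toy_dataset):
    lr = rnc.train_base_learner(
        toy_dataset, np.arange(toy_dataset.n_subjects), np.array([0, 1]), "mlp", None, 0
    )
    assert np.mean(lr.predict(toy_dataset.features) == toy_dataset.labels) == 1.0


def test_constant_features_fall_back_to_majority_class():
    n = 30
    y = np.where(np.arange(n) < 20, 1, -1)  # HC majority
    X = np.full((n, 2), 0.7)  # constant features carry no information
    D = rnc.LabeledDataset(X, y, tuple(f"s{i}" for i in range(n)))
    lr = rnc.train_base_learner(D, np.arange(n), np.array([0, 1]), "logistic", None, 0)
    majority = 1 if np.sum(y == 1) >= np.sum(y == -1) else -1
    preds = lr.predict(D.features)
    assert np.mean(preds == majority) == 1.0


def test_single_class_subset_is_an_error(toy_dataset):
    rows = np.flatnonzero(toy_dataset.labels == 1)
    with pytest.raises(ValueError):
        rnc.train_base_learner(toy_dataset, rows, np.array([0, 1]), "mlp", None, 0)


def test_shuffled_labels_give_chance_level_held_out_accuracy():
    """Permutation oracle: no label-feature association -> accuracy ~ 0.5."""
    rng = np.random.default_rng(42)
    accs = []
    for rep in range(50):
        n = 40
        y = np.repeat([1, -1], n // 2)
        rng.shuffle(y)
        X = rng.normal(size=(n, 5))
        D = rnc.LabeledDataset(X, y, tuple(f"s{i}" for i in range(n)))
        train_rows = np.arange(0, 30)
        if np.unique(y[train_rows]).size < 2:
            continue
        lr = rnc.train_base_learner(D, train_rows, np.arange(5), "logistic", None, rep)
        accs.append(np.mean(lr.predict(X[30:]) == y[30:]))
    # binomial sampling error of the mean over ~50 x 10 held-out predictions
    assert abs(np.mean(accs) - 0.5) < 0.08


def test_training_rows_score_at_least_held_out_on_average():
    gaps = []
    for rep in range(20):
        D = make_dataset(30, n_features=8, seed=rep, informative=0, shift=1.0)
        train_rows, test_rows = np.arange(20), np.arange(20, 30)
        lr = rnc.train_base_learner(D, train_rows, np.arange(8), "mlp", None, rep)
        acc_train = np.mean(lr.predict(D.features[train_rows]) == D.labels[train_rows])
        acc_test = np.mean(lr.predict(D.features[test_rows]) == D.labels[test_rows])
        gaps.append(acc_train - acc_test)
    assert np.mean(gaps) >= 0


# ------------------------------------------------------------------ ensemble


def brute_force_vote(vote_matrix):
    """Independent tally oracle: count +1s and -1s per subject."""
    out = []
    for col in np.asarray(vote_matrix).T:
        plus = int(np.sum(col == 1))
        minus = int(np.sum(col == -1))
        out.append(1 if plus >= minus else -1)
    return np.array(out)


def test_majority_vote_simple_cases():
    cluster = stub_cluster([[1], [1], [-1]])
    assert rnc.predict_majority(cluster, np.zeros((1, 3)))[0] == 1
    tie = stub_cluster([[1], [-1]])
    assert rnc.predict_majority(tie, np.zeros((1, 3)))[0] == 1  # ties go to +1 (HC)


@given(
    st.integers(1, 9).flatmap(
        lambda k: st.integers(1, 8).flatmap(
            lambda n: st.lists(
                st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n),
                min_size=k,
                max_size=k,
            )
        )
    )
)
def test_majority_vote_matches_brute_force_tally(vote_matrix):
    votes = np.asarray(vote_matrix)
    cluster = stub_cluster(votes)
    X = np.zeros((votes.shape[1], 3))
    assert np.array_equal(rnc.predict_majority(cluster, X), brute_force_vote(votes))


def test_cluster_accuracy_is_correct_fraction():
    votes = np.ones((3, 13), dtype=int)
    labels = np.ones(13, dtype=int)
    labels[0] = -1  # one subject misvoted: C=12, N2=13
    test = rnc.LabeledDataset(np.zeros((13, 3)), labels, tuple(f"t{i}" for i in range(13)))
    assert rnc.cluster_accuracy(stub_cluster(votes), test) == pytest.approx(12 / 13)
    assert f"{rnc.cluster_accuracy(stub_cluster(votes), test):.6f}" == "0.923077"


def test_constant_positive_cluster_scores_half_on_balanced_test():
    votes = np.ones((5, 10), dtype=int)
    labels = np.repeat([1, -1], 5)
    test = rnc.LabeledDataset(np.zeros((10, 3)), labels, tuple(f"t{i}" for i in range(10)))
    assert rnc.cluster_accuracy(stub_cluster(votes), test) == 0.5


def test_cluster_accuracy_rejects_empty_test():
    with pytest.raises(ValueError):
        rnc.cluster_accuracy(
            stub_cluster([[1]]),
            rnc.LabeledDataset(np.zeros((0, 3)), np.zeros(0, dtype=int), ()),
        )


def test_per_learner_accuracies_match_hand_tally():
    votes = np.array([[1, 1, -1, -1], [1, -1, 1, -1], [-1, -1, -1, -1]])
    labels = np.array([1, 1, -1, -1])
    test = rnc.LabeledDataset(np.zeros((4, 3)), labels, ("a", "b", "c", "d"))
    cluster = rnc.evaluate_learners(stub_cluster(votes), test)
    assert [lr.test_accuracy for lr in cluster.learners] == [1.0, 0.5, 0.5]
    summary = learner_accuracy_summary(cluster)
    assert summary["min"] == 0.5 and summary["max"] == 1.0
    assert summary["mean"] == pytest.approx(2 / 3)


def test_unevaluated_cluster_raises_state_error():
    with pytest.raises(UnevaluatedClusterError):
        rnc.select_significant_learners(stub_cluster([[1]]), 0.6)


def test_build_cluster_is_deterministic_and_correctly_sized():
    D = make_dataset(20, n_features=50, seed=1, informative=0)
    cfg = rnc.ClusterConfig(k=6, n_samples=12, m_features=9, seed=17, learner_kind="logistic")
    a = rnc.build_cluster(D, cfg)
    b = rnc.build_cluster(D, cfg)
    assert len(a) == 6
    for la, lb in zip(a.learners, b.learners):
        assert np.array_equal(la.feature_indices, lb.feature_indices)
        assert np.array_equal(la.sample_indices, lb.sample_indices)
        assert la.feature_indices.size == 9 and la.sample_indices.size == 12
    test = make_dataset(10, n_features=50, seed=2, informative=0)
    rnc.evaluate_learners(a, test)
    rnc.evaluate_learners(b, test)
    assert [l.test_accuracy for l in a.learners] == [l.test_accuracy for l in b.learners]
    assert rnc.cluster_accuracy(a, test) == rnc.cluster_accuracy(b, test)


def test_accuracy_invariant_to_learner_order():
    rng = np.random.default_rng(0)
    votes = rng.choice([-1, 1], size=(7, 6))
    labels = rng.choice([-1, 1], size=6)
    test = rnc.LabeledDataset(np.zeros((6, 3)), labels, tuple(f"t{i}" for i in range(6)))
    acc1 = rnc.cluster_accuracy(stub_cluster(votes), test)
    acc2 = rnc.cluster_accuracy(stub_cluster(votes[::-1]), test)
    assert acc1 == acc2


def test_predict_majority_rejects_wrong_width():
    with pytest.raises(ValueError):
        rnc.predict_majority(stub_cluster([[1]]), np.zeros((1, 5)))


def test_out_of_bag_evaluation_uses_unseen_rows():
    D = make_dataset(12, n_features=4, seed=0, informative=0)
    cfg = rnc.ClusterConfig(k=3, n_samples=8, m_features=2, seed=3, learner_kind="logistic")
    cluster = rnc.build_cluster(D, cfg)
    rnc.evaluate_learners_oob(cluster, D)
    for lr, oob in zip(cluster.learners, out_of_bag_sets(cluster, D)):
        assert not set(oob) & set(lr.sample_indices)
        assert lr.test_accuracy is not None
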
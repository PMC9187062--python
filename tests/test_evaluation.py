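"""ROC/AUC, logistic combinations, classification metrics, clustering."""

import numpy as np
import pytest

from mirpanel import (
    best_combination,
    classification_metrics,
    fit_combination,
    hierarchical_cluster,
    roc_auc,
)

from conftest import make_matrix


def _pairs_auc(scores, labels):
    """Brute-force Mann-Whitney AUC: concordant pairs plus half the ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ----------------------------------------------------------------------
# ROC / AUC
# ----------------------------------------------------------------------
def test_roc_examples():
    assert roc_auc([1, 2, 3, 9, 10, 11], [0, 0, 0, 1, 1, 1]).auc == 1.0
    assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)
    r = roc_auc([0.1, 0.9, 0.4], [0, 1, 1])
    assert roc_auc([-0.1, -0.9, -0.4], [0, 1, 1]).auc == pytest.approx(1 - r.auc)
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([1.0, 2.0], [1, 1])


def test_roc_curve_is_monotone():
    rng = np.random.default_rng(2)
    r = roc_auc(rng.normal(size=40), rng.integers(0, 2, size=40) |
                np.r_[1, np.zeros(39, dtype=int)])
    assert np.all(np.diff(r.fpr) >= 0)
    assert np.all(np.diff(r.tpr) >= 0)


def test_auc_equals_pair_counting_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = rng.integers(4, 51)
        y = np.zeros(n, dtype=int)
        y[: rng.integers(1, n)] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            continue
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        assert roc_auc(scores, y).auc == pytest.approx(_pairs_auc(scores, y))


# ----------------------------------------------------------------------
# logistic combinations
# ----------------------------------------------------------------------
def _cohort(seed=0, n=60, informative=("m1",), noise=("m2",), delta=3.0):
    rng = np.random.default_rng(seed)
    probes = list(informative) + list(noise)
    X = rng.normal(size=(len(probes), n))
    labels = ["cancer"] * (n // 2) + ["non_cancer"] * (n - n // 2)
    for i, p in enumerate(probes):
        if p in informative:
            X[i, : n // 2] += delta
    return make_matrix(X, probe_ids=probes, labels=labels,
                       types=["lung" if l == "cancer" else "none"
                              for l in labels])


def test_single_covariate_model_has_the_covariates_own_auc():
    m = _cohort(seed=1, delta=1.0)
    model = fit_combination(m, ["m1"])
    X, y, _ = m.to_xy(probes=["m1"])
    assert model.training_auc == pytest.approx(roc_auc(X[:, 0], y).auc)


def test_planted_up_marker_gets_positive_coefficient():
    signs = []
    for seed in range(5):
        m = _cohort(seed=seed, delta=2.0)
        model = fit_combination(m, ["m1", "m2"])
        signs.append(model.coefficients[model.subset.index("m1")] > 0)
    assert all(signs)


def test_duplicated_covariate_matches_single_column_auc():
    m = _cohort(seed=3, delta=1.5)
    dup = make_matrix(
        np.vstack([m.values.loc["m1"], m.values.loc["m1"]]),
        probe_ids=["m1", "m1b"], labels=list(m.samples["label"]),
        types=list(m.samples["cancer_type"]))
    single = fit_combination(m, ["m1"])
    double = fit_combination(dup, ["m1", "m1b"])
    assert double.training_auc == pytest.approx(single.training_auc, abs=1e-6)


def test_constant_covariate_is_dropped_with_warning():
    m = _cohort(seed=4)
    vals = m.values.copy()
    vals.loc["m2"] = 1.0
    m2 = make_matrix(vals.to_numpy(), probe_ids=list(vals.index),
                     labels=list(m.samples["label"]),
                     types=list(m.samples["cancer_type"]))
    with pytest.warns(UserWarning, match="constant"):
        model = fit_combination(m2, ["m1", "m2"])
    assert model.coefficients[model.subset.index("m2")] == 0.0


def test_best_combination_counts_subsets_and_handles_singletons():
    m = _cohort(seed=5, informative=("a", "b"), noise=("c", "d", "e"))
    train, val = m.subset_samples(m.sample_ids[::2]), m.subset_samples(
        m.sample_ids[1::2])
    model, report, table = best_combination(train, val, ["a", "b", "c", "d", "e"])
    assert len(table) == 2**5 - 1
    single, rep, tab = best_combination(train, val, ["a"])
    assert single.subset == ["a"] and len(tab) == 1
    with pytest.raises(ValueError, match="exhaustive"):
        best_combination(train, val, [f"x{i}" for i in range(16)])


def test_dominant_marker_always_enters_winning_subset():
    hits = 0
    for seed in range(5):
        m = _cohort(seed=seed, n=80, informative=("good",),
                    noise=("n1", "n2"), delta=3.0)
        train = m.subset_samples(m.sample_ids[::2])
        val = m.subset_samples(m.sample_ids[1::2])
        model, _, _ = best_combination(train, val, ["good", "n1", "n2"])
        hits += "good" in model.subset
    assert hits == 5


# ----------------------------------------------------------------------
# classification metrics
# ----------------------------------------------------------------------
def test_metrics_identities():
    r = classification_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert r.accuracy == r.sensitivity == r.specificity == 1.0
    # TP=2, FN=0, TN=1, FP=1
    r = classification_metrics([0.9, 0.8, 0.7, 0.2], [1, 1, 0, 0])
    assert (r.tp, r.fp, r.tn, r.fn) == (2, 1, 1, 0)
    assert r.sensitivity == 1.0
    assert r.specificity == pytest.approx(0.5)
    assert r.accuracy == pytest.approx(0.75)
    # threshold 0 calls everything cancer
    r = classification_metrics([0.9, 0.1], [1, 0], threshold=0.0)
    assert r.sensitivity == 1.0 and r.specificity == 0.0
    with pytest.raises(ValueError):
        classification_metrics([1.2], [1])


# ----------------------------------------------------------------------
# hierarchical clustering
# ----------------------------------------------------------------------
def test_two_separated_blobs_cluster_exactly():
    rng = np.random.default_rng(6)
    X = np.hstack([rng.normal(0, 0.1, size=(3, 10)),
                   rng.normal(10, 0.1, size=(3, 10))])
    m = make_matrix(X, labels=["cancer"] * 10 + ["non_cancer"] * 10,
                    types=["lung"] * 10 + ["none"] * 10)
    labels, Z = hierarchical_cluster(m, m.probe_ids, n_clusters=2)
    blob = labels.iloc[:10]
    assert blob.nunique() == 1 and labels.iloc[10:].nunique() == 1
    assert blob.iloc[0] != labels.iloc[10]


def test_duplicate_samples_merge_at_height_zero():
    m = make_matrix(np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 7.0]]),
                    labels=["cancer", "cancer", "non_cancer"],
                    types=["lung", "lung", "none"])
    _, Z = hierarchical_cluster(m, m.probe_ids, n_clusters=2)
    assert Z[0, 2] == 0.0


def test_single_sample_forms_one_cluster():
    m = make_matrix([[1.0], [2.0]], labels=["cancer"], types=["lung"])
    labels, _ = hierarchical_cluster(m, m.probe_ids, n_clusters=1)
    assert list(labels) == [1]
    with pytest.raises(ValueError):
        hierarchical_cluster(m, m.probe_ids, n_clusters=0)
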
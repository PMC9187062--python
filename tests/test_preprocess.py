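"""Presence calling, quantile normalization, deduplication, and the
stratified split."""

import numpy as np
import pytest

from mirpanel import (
    QuantileNormalizer,
    SplitPlan,
    apply_absence_policy,
    call_presence,
    curate_deduplicate,
    generate_cohort,
    quantile_normalize,
    stratified_split,
)
from mirpanel.config import SyntheticConfig
from mirpanel.preprocess import split_manifest

from conftest import make_matrix


# ----------------------------------------------------------------------
# presence calling
# ----------------------------------------------------------------------
def _with_controls(signals, controls):
    """One sample whose negative controls take the given values."""
    sig = np.asarray(signals, dtype=float)[:, None]
    ctl = np.asarray(controls, dtype=float)[:, None]
    probes = [f"p{i}" for i in range(len(signals))]
    negs = [f"NEGCTRL-{i}" for i in range(len(controls))]
    return make_matrix(np.vstack([sig, ctl]), probe_ids=probes + negs,
                       labels=["cancer"], types=["lung"])


def test_presence_threshold_with_zero_spread_controls():
    # controls {10,10,10}: threshold 10; 12 is present (value 2), 10 absent
    m = _with_controls([12.0, 10.0], [10.0, 10.0, 10.0])
    out = call_presence(m)
    assert out.values.loc["p0", "s0"] == pytest.approx(2.0)
    assert np.isnan(out.values.loc["p1", "s0"])
    assert "NEGCTRL-0" not in out.probe_ids


def test_presence_threshold_mean_plus_two_sd():
    # controls {8,10,12}: mean 10, SD 2, threshold 14; 14 absent, 15 -> 5
    m = _with_controls([14.0, 15.0], [8.0, 10.0, 12.0])
    out = call_presence(m)
    assert np.isnan(out.values.loc["p0", "s0"])
    assert out.values.loc["p1", "s0"] == pytest.approx(5.0)


def test_all_signals_below_threshold_is_not_an_error():
    m = _with_controls([1.0, 2.0], [8.0, 10.0, 12.0])
    out = call_presence(m)
    assert out.values.isna().to_numpy().all()


def test_presence_requires_negative_controls():
    m = make_matrix([[1.0, 2.0]])
    with pytest.raises(ValueError, match="negative-control"):
        call_presence(m)


def test_retained_values_are_never_negative():
    cfg = SyntheticConfig.desk_scale(seed=2, n_probes=50)
    matrix, _ = generate_cohort(cfg)
    out = call_presence(matrix)
    vals = out.values.to_numpy()
    assert np.nanmin(vals) >= 0.0


# ----------------------------------------------------------------------
# quantile normalization
# ----------------------------------------------------------------------
def test_identical_samples_are_a_fixed_point():
    m = make_matrix(np.tile([[1.0], [5.0], [9.0]], (1, 4)))
    out = quantile_normalize(m)
    assert np.allclose(out.values.to_numpy(), m.values.to_numpy())


def test_two_sample_rank_mean_oracle():
    m = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
                    labels=["cancer", "non_cancer"])
    out = quantile_normalize(m)
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    assert np.allclose(out.values.to_numpy(), expected)


def test_sample_order_permutation_invariance():
    rng = np.random.default_rng(0)
    m = make_matrix(rng.normal(size=(6, 5)))
    out = quantile_normalize(m)
    perm = list(reversed(m.sample_ids))
    out_perm = quantile_normalize(m.subset_samples(perm))
    for s in m.sample_ids:
        assert np.allclose(out.values[s], out_perm.values[s])


def test_normalized_samples_share_one_multiset():
    rng = np.random.default_rng(1)
    m = make_matrix(rng.normal(size=(40, 7)))
    out = quantile_normalize(m)
    X = out.values.to_numpy()
    ref = np.sort(X[:, 0])
    for j in range(X.shape[1]):
        assert np.allclose(np.sort(X[:, j]), ref)
    assert np.allclose(X.mean(axis=0), X.mean(axis=0)[0])


def test_ties_receive_mean_of_spanned_quantiles():
    # sample 0 has a tie at ranks 1-2; reference quantiles are (2, 3, 9)
    m = make_matrix(np.array([[1.0, 3.0], [1.0, 5.0], [8.0, 10.0]]),
                    labels=["cancer", "non_cancer"])
    out = quantile_normalize(m)
    ref = np.array([2.0, 3.0, 9.0])
    assert np.allclose(out.values["s1"], ref)
    assert out.values.loc["p0", "s0"] == pytest.approx(2.5)  # mean of 2 and 3
    assert out.values.loc["p1", "s0"] == pytest.approx(2.5)
    assert out.values.loc["p2", "s0"] == pytest.approx(9.0)


def test_absent_values_are_rejected_with_guidance():
    m = make_matrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
    with pytest.raises(ValueError, match="absence policy"):
        quantile_normalize(m)
    dense = apply_absence_policy(m, max_absent_frac=0.5)
    assert dense.values.loc["p0", "s1"] == 0.0
    quantile_normalize(dense)  # no longer raises


def test_absence_policy_drops_mostly_absent_probes():
    m = make_matrix(np.array([[np.nan, np.nan, 1.0],
                              [1.0, 2.0, 3.0]]),
                    labels=["cancer", "cancer", "non_cancer"],
                    types=["lung", "lung", "none"])
    out = apply_absence_policy(m, max_absent_frac=0.5)
    assert out.probe_ids == ["p1"]


def test_normalizer_learns_reference_from_training_rows():
    rng = np.random.default_rng(4)
    X_train = rng.normal(size=(10, 8))
    qn = QuantileNormalizer().fit(X_train)
    X_new = rng.normal(5, 3, size=(2, 8))
    out = qn.transform(X_new)
    for row in out:
        assert np.allclose(np.sort(row), qn.reference_)


# ----------------------------------------------------------------------
# deduplication
# ----------------------------------------------------------------------
def test_deduplicate_keeps_first_occurrence():
    a = make_matrix([[1.0, 2.0, 3.0]], sample_ids=["x", "y", "z"],
                    labels=["cancer", "cancer", "non_cancer"],
                    types=["lung", "lung", "none"])
    b = make_matrix([[9.0, 4.0, 5.0]], sample_ids=["z", "u", "v"],
                    labels=["non_cancer"] * 3, types=["none"] * 3)
    merged = curate_deduplicate([a, b])
    assert merged.n_samples == 5
    assert merged.values.loc["p0", "z"] == 3.0  # first batch wins


def test_deduplicate_disjoint_batches_concatenate():
    a = make_matrix([[1.0, 2.0]], sample_ids=["a1", "a2"])
    b = make_matrix([[3.0, 4.0]], sample_ids=["b1", "b2"])
    merged = curate_deduplicate([a, b])
    assert merged.sample_ids == ["a1", "a2", "b1", "b2"]


def test_deduplicate_requires_identical_probe_lists():
    a = make_matrix([[1.0, 2.0]], probe_ids=["p0"])
    b = make_matrix([[1.0, 2.0]], probe_ids=["q0"],
                    sample_ids=["t0", "t1"])
    with pytest.raises(ValueError, match="probe lists differ"):
        curate_deduplicate([a, b])


# ----------------------------------------------------------------------
# stratified split
# ----------------------------------------------------------------------
def test_split_fraction_arithmetic():
    m = make_matrix(np.arange(10, dtype=float)[None, :],
                    labels=["cancer"] * 10, types=["lung"] * 10)
    plan = SplitPlan(fraction_by_type={"lung": 0.8}, seed=0)
    train, val = stratified_split(m, plan)
    assert (train.n_samples, val.n_samples) == (8, 2)
    assert set(train.sample_ids) | set(val.sample_ids) == set(m.sample_ids)
    assert set(train.sample_ids) & set(val.sample_ids) == set()


def test_reference_plan_training_counts_round_half_up():
    """On the full reference cohort profile the default plan places 2252
    cancer samples in training: prostate 324, ovarian 224, bladder 274,
    hepatocellular 242, the remaining nine types 1188."""
    cfg = SyntheticConfig(n_probes=1, n_pan_markers=0, n_type_markers=0,
                          n_neg_controls=0, seed=0)
    matrix, _ = generate_cohort(cfg)
    train, val = stratified_split(matrix, SplitPlan(seed=0))
    tr = train.samples
    counts = tr[tr["label"] == "cancer"]["cancer_type"].value_counts()
    assert counts["prostate"] == 324
    assert counts["ovarian"] == 224
    assert counts["bladder"] == 274
    assert counts["hepatocellular"] == 242
    assert counts.sum() == 2252
    assert counts.sum() - (324 + 224 + 274 + 242) == 1188
    # per-type totals preserved between the two subsets
    va = val.samples
    total = counts.add(va[va["label"] == "cancer"]["cancer_type"]
                       .value_counts(), fill_value=0)
    assert total["prostate"] == 809 and total.sum() == 3352


def test_split_is_seed_deterministic():
    m = make_matrix(np.arange(20, dtype=float)[None, :],
                    labels=["cancer"] * 10 + ["non_cancer"] * 10,
                    types=["lung"] * 10 + ["none"] * 10)
    plan = SplitPlan(fraction_by_type={"lung": 0.7}, non_cancer_fraction=0.5,
                     seed=42)
    t1, _ = stratified_split(m, plan)
    t2, _ = stratified_split(m, plan)
    assert t1.sample_ids == t2.sample_ids


def test_split_errors():
    m = make_matrix([[1.0]], labels=["cancer"], types=["lung"])
    with pytest.raises(ValueError, match="<2 samples"):
        stratified_split(m, SplitPlan(fraction_by_type={"lung": 0.5}))
    m2 = make_matrix([[1.0, 2.0]], labels=["cancer"] * 2, types=["glioma"] * 2)
    with pytest.raises(ValueError, match="no training fraction"):
        stratified_split(m2, SplitPlan(fraction_by_type={"lung": 0.5}))


def test_split_manifest_covers_every_sample():
    m = make_matrix(np.arange(6, dtype=float)[None, :],
                    labels=["cancer"] * 4 + ["non_cancer"] * 2,
                    types=["lung"] * 4 + ["none"] * 2)
    plan = SplitPlan(fraction_by_type={"lung": 0.5}, non_cancer_fraction=0.5)
    train, val = stratified_split(m, plan)
    manifest = split_manifest(train, val)
    assert sorted(manifest["sample_id"]) == sorted(m.sample_ids)
    assert set(manifest["subset"]) == {"train", "validation"}
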
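"""Microarray preprocessing: presence calling against negative controls,
background subtraction, cross-sample quantile normalization, duplicate-sample
curation, and the per-type stratified train/validation split.
"""

from __future__ import annotations

import logging
from typing import List

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .config import SplitPlan, round_half_up
from .matrix import CLASS_CANCER, ExpressionMatrix
from .simulate import NEG_CONTROL_PREFIX

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# presence calling
# ----------------------------------------------------------------------
def call_presence(matrix: ExpressionMatrix,
                  neg_control_prefix: str = NEG_CONTROL_PREFIX) -> ExpressionMatrix:
    """Presence call and background subtraction against negative controls.

    Per sample, the detection threshold is ``mean + 2*SD`` of that sample's
    negative-control probe values.  Signals strictly above the threshold are
    retained background-subtracted (signal minus the negative-control mean);
    signals at or below it become absent (NaN).  Negative-control probes are
    removed from the output.  Retained values are never negative, since
    ``signal - mean > 2*SD >= 0``.
    """
    neg_rows = [p for p in matrix.probe_ids if str(p).startswith(neg_control_prefix)]
    if not neg_rows:
        raise ValueError(
            f"no negative-control probes with prefix {neg_control_prefix!r}; "
            "skip the presence-calling stage for data without controls"
        )
    if len(neg_rows) < 2:
        raise ValueError("need at least 2 negative-control probes per sample")
    neg = matrix.values.loc[neg_rows]
    mean = neg.mean(axis=0)
    sd = neg.std(axis=0, ddof=1)
    threshold = mean + 2.0 * sd

    signal = matrix.values.drop(index=neg_rows)
    present = signal.gt(threshold, axis=1)
    out = signal.sub(mean, axis=1).where(present)
    n_absent = int((~present).to_numpy().sum())
    logger.info("presence call: %d/%d measurements absent",
                n_absent, out.size)
    return ExpressionMatrix(out, matrix.samples)


def apply_absence_policy(matrix: ExpressionMatrix,
                         max_absent_frac: float = 0.5) -> ExpressionMatrix:
    """Drop probes absent in more than ``max_absent_frac`` of samples and set
    the remaining absences to 0, densifying the matrix for normalization."""
    absent_frac = matrix.values.isna().mean(axis=1)
    keep = absent_frac[absent_frac <= max_absent_frac].index
    dropped = matrix.n_probes - len(keep)
    if dropped:
        logger.info("absence policy: dropped %d probes absent in >%.0f%% of samples",
                    dropped, 100 * max_absent_frac)
    return ExpressionMatrix(matrix.values.loc[keep].fillna(0.0), matrix.samples)


# ----------------------------------------------------------------------
# quantile normalization
# ----------------------------------------------------------------------
class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every sample's value distribution onto a common reference.

    ``fit`` learns the reference distribution -- the across-sample mean of
    sorted value vectors -- from rows of ``X`` (one row per sample);
    ``transform`` replaces each row by the reference values at its ranks,
    with tied values receiving the mean of the reference quantiles they
    span.  ``fit_transform`` on the full cohort is classical cross-sample
    quantile normalization: afterwards every sample holds the same multiset
    of values (exactly so in the absence of ties).
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, ensure_min_features=1)
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        ref = self.reference_
        out = np.empty_like(X, dtype=float)
        for i, row in enumerate(X):
            order = np.argsort(row, kind="stable")
            mapped = np.empty_like(ref)
            mapped[order] = ref
            # ties: average the reference values spanned by each tied group
            uniq, inv, counts = np.unique(row, return_inverse=True,
                                          return_counts=True)
            if len(uniq) < len(row):
                sums = np.bincount(inv, weights=mapped)
                mapped = (sums / counts)[inv]
            out[i] = mapped
        return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples of a matrix jointly.

    Requires a dense matrix; run :func:`apply_absence_policy` first if the
    presence call left absent values.
    """
    if matrix.values.isna().to_numpy().any():
        raise ValueError(
            "matrix contains absent values; apply the absence policy "
            "(apply_absence_policy) before quantile normalization"
        )
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = matrix.values.to_numpy().T  # samples as rows
    normalized = QuantileNormalizer().fit_transform(X)
    frame = pd.DataFrame(normalized.T, index=matrix.values.index,
                         columns=matrix.values.columns)
    return ExpressionMatrix(frame, matrix.samples)


# ----------------------------------------------------------------------
# duplicate-sample curation
# ----------------------------------------------------------------------
def curate_deduplicate(matrices: List[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge batches into one cohort, keeping the first occurrence of every
    sample id in input order.  All batches must share an identical probe list
    (no probe harmonization is attempted)."""
    if not matrices:
        raise ValueError("no matrices to merge")
    probes = matrices[0].probe_ids
    for m in matrices[1:]:
        if m.probe_ids != probes:
            raise ValueError("probe lists differ between batches; cannot merge")
    seen: dict = {}
    for bi, m in enumerate(matrices):
        for s in m.sample_ids:
            if s in seen:
                first = matrices[seen[s]]
                if not np.array_equal(first.values[s].to_numpy(),
                                      m.values[s].to_numpy(), equal_nan=True):
                    logger.warning(
                        "duplicate sample %r has conflicting values between "
                        "batches %d and %d; keeping first", s, seen[s], bi)
            else:
                seen[s] = bi
    values = {}
    annot = {}
    for s, bi in seen.items():
        values[s] = matrices[bi].values[s]
        annot[s] = matrices[bi].samples.loc[s]
    frame = pd.DataFrame(values)
    frame.index = probes
    samples = pd.DataFrame(annot).T
    return ExpressionMatrix(frame, samples.loc[frame.columns])


# ----------------------------------------------------------------------
# stratified split
# ----------------------------------------------------------------------
def stratified_split(matrix: ExpressionMatrix, plan: SplitPlan):
    """Split into ``(train, validation)`` by per-type training fractions.

    For each cancer type t, ``round_half_up(n_t * fraction_t)`` samples are
    drawn uniformly without replacement into training; non-cancer samples
    use ``plan.non_cancer_fraction``.  Deterministic for a fixed
    ``plan.seed``; train and validation are disjoint and exhaustive, and
    per-type totals are preserved.
    """
    rng = np.random.default_rng(plan.seed)
    samples = matrix.samples
    train_ids: list = []
    groups = []
    for t in sorted(set(samples.loc[samples["label"] == CLASS_CANCER,
                                    "cancer_type"])):
        if t not in plan.fraction_by_type:
            raise ValueError(f"split plan has no training fraction for type {t!r}")
        ids = list(samples.index[samples["cancer_type"] == t])
        groups.append((t, ids, plan.fraction_by_type[t]))
    control_ids = list(samples.index[samples["label"] != CLASS_CANCER])
    if control_ids:
        groups.append(("non_cancer", control_ids, plan.non_cancer_fraction))

    for name, ids, frac in groups:
        if len(ids) < 2:
            raise ValueError(f"cannot split group {name!r} with <2 samples")
        n_train = round_half_up(len(ids) * frac)
        picked = rng.choice(len(ids), size=n_train, replace=False)
        train_ids += [ids[i] for i in sorted(picked)]

    train_set = set(train_ids)
    order = list(matrix.sample_ids)
    train = matrix.subset_samples([s for s in order if s in train_set])
    validation = matrix.subset_samples([s for s in order if s not in train_set])
    logger.info("stratified split: %d training / %d validation samples (seed=%d)",
                train.n_samples, validation.n_samples, plan.seed)
    return train, validation


def split_manifest(train: ExpressionMatrix,
                   validation: ExpressionMatrix) -> pd.DataFrame:
    """Audit table of the split: one row per sample with its subset."""
    rows = [(s, "train") for s in train.sample_ids]
    rows += [(s, "validation") for s in validation.sample_ids]
    return pd.DataFrame(rows, columns=["sample_id", "subset"])
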
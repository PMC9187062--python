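"""Probe-by-sample expression container shared by every pipeline stage.

An :class:`ExpressionMatrix` holds a dense probe x sample grid of
log-scale intensities together with per-sample annotations (cancer /
non_cancer label, cancer type, batch).  Absent values -- probes that
failed the presence call in a sample -- are represented as NaN.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CLASS_CANCER = "cancer"
CLASS_NON_CANCER = "non_cancer"
NO_TYPE = "none"

#: annotation columns every sample must carry
ANNOTATION_COLUMNS = ("label", "cancer_type", "batch")


class ValidationError(ValueError):
    """Raised when a matrix violates its structural invariants."""


class ExpressionMatrix:
    """Dense probe x sample intensity grid with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
        NaN encodes an absent (not-detected) measurement.
    samples
        DataFrame indexed by sample id with columns ``label``
        (``cancer`` / ``non_cancer``), ``cancer_type`` (one of the
        cancer-type labels, or ``none`` for non-cancer samples) and
        ``batch``.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        values = values.copy()
        samples = samples.copy()
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicated probe id: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValidationError(f"duplicated sample id: {dup!r}")
        missing = [c for c in ANNOTATION_COLUMNS if c not in samples.columns]
        if missing:
            raise ValidationError(f"missing annotation columns: {missing}")
        if list(samples.index) != list(values.columns):
            raise ValidationError(
                "sample annotations must cover exactly the matrix columns, in order"
            )
        bad = set(samples["label"]) - {CLASS_CANCER, CLASS_NON_CANCER}
        if bad:
            raise ValidationError(f"unknown class labels: {sorted(bad)}")
        is_cancer = samples["label"] == CLASS_CANCER
        has_type = samples["cancer_type"].astype(str) != NO_TYPE
        if (is_cancer != has_type).any():
            offender = samples.index[is_cancer != has_type][0]
            raise ValidationError(
                f"sample {offender!r}: cancer_type must be set iff label is cancer"
            )
        self.values = values.astype(float)
        self.samples = samples

    # ------------------------------------------------------------------
    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def labels(self) -> pd.Series:
        """Per-sample class labels (``cancer`` / ``non_cancer``)."""
        return self.samples["label"]

    # ------------------------------------------------------------------
    def subset_probes(self, probe_ids: Sequence) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise KeyError(f"unknown probes: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.samples)

    def subset_samples(self, sample_ids: Sequence) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing[:5]}")
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def drop_probes(self, probe_ids: Iterable) -> "ExpressionMatrix":
        drop = set(probe_ids)
        keep = [p for p in self.values.index if p not in drop]
        return ExpressionMatrix(self.values.loc[keep], self.samples)

    # ------------------------------------------------------------------
    def to_xy(self, probes: Sequence | None = None):
        """Samples-by-features view for scikit-learn estimators.

        Returns ``(X, y, feature_names)`` where ``X`` is an
        ``(n_samples, n_probes)`` float array and ``y`` is 1 for cancer,
        0 for non-cancer.
        """
        sub = self if probes is None else self.subset_probes(probes)
        X = sub.values.to_numpy().T
        y = (sub.samples["label"] == CLASS_CANCER).to_numpy().astype(int)
        return X, y, list(sub.values.index)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            list(self.values.index) == list(other.values.index)
            and list(self.values.columns) == list(other.values.columns)
            and np.array_equal(
                self.values.to_numpy(), other.values.to_numpy(), equal_nan=True
            )
            and self.samples.astype(str).equals(other.samples.astype(str))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_cancer = int((self.samples["label"] == CLASS_CANCER).sum())
        return (
            f"ExpressionMatrix({self.n_probes} probes x {self.n_samples} samples, "
            f"{n_cancer} cancer)"
        )
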
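import numpy as np
import pandas as pd
import pytest

from mirpanel.matrix import ExpressionMatrix


def make_matrix(values, probe_ids=None, sample_ids=None, labels=None,
                types=None, batches=None):
    """Build a small ExpressionMatrix from a 2-D array (probes x samples)."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    if labels is None:
        labels = ["cancer" if i < n_samples // 2 else "non_cancer"
                  for i in range(n_samples)]
    if types is None:
        types = ["lung" if lab == "cancer" else "none" for lab in labels]
    batches = batches or ["b0"] * n_samples
    frame = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"label": labels, "cancer_type": types, "batch": batches},
        index=sample_ids)
    return ExpressionMatrix(frame, samples)


@pytest.fixture
def tiny_matrix():
    """3 probes x 4 samples, two classes."""
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(8, 1, size=(3, 4)))
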
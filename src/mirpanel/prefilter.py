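"""Per-miRNA two-group Welch testing with BH-FDR control and top-k selection.

All cancer types are pooled against non-cancer at this stage; the ranking
(ascending q, then p, then probe id) makes the top-k candidate list
reproducible under ties.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def welch_t(group_a, group_b):
    """Welch's unequal-variance t-test; returns ``(t, df, p)``.

    t = (mean_a - mean_b) / sqrt(v_a/n_a + v_b/n_b) with the
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    Accepts 1-D groups or 2-D arrays (rows tested independently).
    Degenerate cases: both groups constant with equal means -> t=0, p=1;
    both constant with unequal means -> p=0 (infinite t).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    zero_var = denom == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & (diff == 0), 0.0, t)
        t = np.where(zero_var & (diff != 0), np.sign(diff) * np.inf, t)
    df = np.where(zero_var, np.nan, df)
    p = np.where(zero_var, np.where(diff == 0, 1.0, 0.0),
                 2.0 * stats.t.sf(np.abs(t), np.where(zero_var, 1.0, df)))
    if np.asarray(group_a).ndim == 1:
        return float(t[0]), float(df[0]), float(p[0])
    return t, df, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_probes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Welch-test every probe (cancer vs non-cancer) and attach BH q-values.

    Returns a DataFrame with columns ``probe_id, t, df, p, q, rank`` where
    rank orders by ascending q, then p, then probe id.
    """
    X, y, names = matrix.to_xy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    t, df, p = welch_t(X[y == 1].T, X[y == 0].T)
    q = bh_fdr(p)
    res = pd.DataFrame({"probe_id": names, "t": t, "df": df, "p": p, "q": q})
    res = res.sort_values(["q", "p", "probe_id"], kind="stable")
    res["rank"] = np.arange(1, len(res) + 1)
    return res.reset_index(drop=True)


def select_top_k(results: pd.DataFrame, k: int) -> list:
    """The k best probes by the (q, p, probe_id) ranking; if fewer than k
    probes are available they are all returned with a warning."""
    ordered = results.sort_values("rank", kind="stable")["probe_id"].tolist()
    if k > len(ordered):
        warnings.warn(
            f"requested top {k} of only {len(ordered)} probes; returning all",
            stacklevel=2,
        )
        return ordered
    return ordered[:k]


class WelchTopKSelector(SelectorMixin, BaseEstimator):
    """Feature selector keeping the k features with smallest BH q-value.

    Welch's t-test is applied per feature between the two classes of ``y``;
    q-values are BH-adjusted across features; the top ``k`` by (q, p,
    feature index) are retained.  Fitted attributes: ``t_``, ``df_``,
    ``p_``, ``q_``, ``support_``.
    """

    def __init__(self, k: int = 500):
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("WelchTopKSelector requires exactly 2 classes")
        a, b = X[y == classes[1]].T, X[y == classes[0]].T
        self.t_, self.df_, self.p_ = welch_t(a, b)
        self.q_ = bh_fdr(self.p_)
        order = np.lexsort((np.arange(X.shape[1]), self.p_, self.q_))
        k = min(self.k, X.shape[1])
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[order[:k]] = True
        self.support_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
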
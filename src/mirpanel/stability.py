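"""Random-forest stability selection of "balanced" miRNAs.

The procedure at the heart of the pipeline: many (canonically 100) random
forest models are each trained on an independent class-stratified 80%
subsample of the training set; in every model the candidate probes are
ranked by mean decrease in Gini (impurity-based importance) and the top 10
recorded, together with the model's accuracy on its held-out 20%.  Probes
appearing in the per-model top 10 at least 90 times out of 100 are the
"balanced" markers.  A percentile bootstrap over the per-model accuracies
gives the confidence interval on mean model accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_X_y

from .config import PipelineConfig
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

#: default tuning grid: features considered per split and forest size;
#: the remaining forest parameters stay at library defaults
DEFAULT_GRID = {
    "max_features": ["sqrt", "third", "log2"],
    "n_estimators": [250, 500, 1000],
}


@dataclass
class MarkerPanel:
    """Balanced-marker panel: probes whose top-10 frequency met the threshold."""

    probes: List[str]
    frequencies: Dict[str, int]
    threshold: int

    def __post_init__(self):
        low = [p for p in self.probes if self.frequencies.get(p, 0) < self.threshold]
        if low:
            raise ValueError(f"panel members below threshold: {low}")

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class StabilityResult:
    """Full output of the ensemble run."""

    per_model_top: List[List[str]]
    frequency: Dict[str, int]
    per_model_accuracy: List[float]
    mean_accuracy: float
    ci_low: float
    ci_high: float
    tuned_params: dict
    threshold: int = 90

    def frequency_table(self) -> pd.DataFrame:
        items = sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["probe_id", "frequency"])

    @property
    def panel(self) -> MarkerPanel:
        return select_balanced(self.frequency, self.threshold)


def select_balanced(frequency: Dict[str, int], threshold: int) -> MarkerPanel:
    """Probes with top-10 frequency >= threshold, sorted by descending
    frequency then probe id.  The threshold is inclusive: a probe seen in
    exactly 90 of 100 models counts as balanced."""
    probes = sorted(
        (p for p, f in frequency.items() if f >= threshold),
        key=lambda p: (-frequency[p], p),
    )
    return MarkerPanel(probes=probes,
                       frequencies={p: frequency[p] for p in probes},
                       threshold=threshold)


def bootstrap_ci(values: Sequence[float], n_boot: int = 10_000,
                 level: float = 0.95, seed: int = 0) -> Tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``values``."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot bootstrap an empty accuracy list")
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap replicates: percentiles are "
                      "unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high)


def _resolve_max_features(spec, n_features: int):
    if spec == "third":
        return max(1, n_features // 3)
    return spec


def tune_hyperparameters(X, y, folds: int = 10, seed: int = 0,
                         grid: Optional[dict] = None) -> dict:
    """Grid-search forest hyperparameters by stratified k-fold CV accuracy.

    The grid covers features-per-split in {sqrt(m), m/3, log2(m)} and forest
    sizes {250, 500, 1000}; ties are broken by grid order (first wins), so
    the choice is deterministic for a fixed seed.
    """
    X, y = check_X_y(X, y)
    grid = grid or DEFAULT_GRID
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify "
            f"{folds} folds"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    best = None
    for mf in grid["max_features"]:
        for n_est in grid["n_estimators"]:
            accs = []
            for fold_i, (tr, te) in enumerate(splits):
                rf = RandomForestClassifier(
                    n_estimators=n_est,
                    max_features=_resolve_max_features(mf, X.shape[1]),
                    random_state=seed + fold_i,
                    n_jobs=1,
                )
                rf.fit(X[tr], y[tr])
                accs.append(rf.score(X[te], y[te]))
            mean_acc = float(np.mean(accs))
            logger.debug("grid point max_features=%s n_estimators=%d: CV acc %.4f",
                         mf, n_est, mean_acc)
            if best is None or mean_acc > best[0]:
                best = (mean_acc, {"max_features": mf, "n_estimators": n_est})
    params = dict(best[1])
    params["cv_accuracy"] = best[0]
    logger.info("tuned forest: %s", params)
    return params


class StabilitySelector(BaseEstimator):
    """Stability selection of features by repeated-subsample forest ranking.

    Parameters mirror the canonical procedure: ``n_models`` forests, each
    trained on a class-stratified ``subsample`` fraction of the data and
    scored on the remainder; per model the ``top_n`` features by
    impurity-based importance are tallied (importance ties at the cut are
    broken lexicographically by feature name and logged); features tallied
    at least ``balanced_threshold`` times form the balanced panel.

    Fitted attributes
    -----------------
    tuned_params_ : dict
        Hyperparameters chosen by CV (or the ones supplied).
    frequencies_ : dict feature -> int
        Top-``top_n`` membership counts over the ensemble.
    per_model_top_ : list of list of str
    per_model_accuracy_ : list of float
    mean_accuracy_, ci_low_, ci_high_ : float
        Mean held-out accuracy and its percentile-bootstrap interval.
    panel_ : MarkerPanel
    support_ : bool array over input features (balanced panel membership)
    """

    def __init__(self, n_models: int = 100, subsample: float = 0.8,
                 top_n: int = 10, balanced_threshold: int = 90,
                 cv_folds: int = 10, n_bootstrap: int = 10_000,
                 ci_level: float = 0.95, tune: bool = True,
                 tuning_grid: Optional[dict] = None,
                 base_params: Optional[dict] = None,
                 random_state: Optional[int] = None):
        self.n_models = n_models
        self.subsample = subsample
        self.top_n = top_n
        self.balanced_threshold = balanced_threshold
        self.cv_folds = cv_folds
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.tune = tune
        self.tuning_grid = tuning_grid
        self.base_params = base_params
        self.random_state = random_state

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        X, y = check_X_y(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        n_features = X.shape[1]
        if n_features < self.top_n:
            raise ValueError(
                f"need at least top_n={self.top_n} candidate features, "
                f"got {n_features}"
            )
        names = (list(feature_names) if feature_names is not None
                 else [f"f{i}" for i in range(n_features)])
        if len(names) != n_features:
            raise ValueError("feature_names length mismatch")

        ss = np.random.SeedSequence(self.random_state or 0)
        tune_seed, ens_seed, boot_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        )

        if self.tune:
            self.tuned_params_ = tune_hyperparameters(
                X, y, folds=self.cv_folds, seed=tune_seed, grid=self.tuning_grid)
        else:
            params = {"max_features": "sqrt", "n_estimators": 500}
            params.update(self.base_params or {})
            self.tuned_params_ = params
        mf = _resolve_max_features(self.tuned_params_["max_features"], n_features)
        n_est = self.tuned_params_["n_estimators"]

        name_arr = np.asarray(names)
        lex_order = np.argsort(name_arr, kind="stable")
        per_model_top: List[List[str]] = []
        accuracies: List[float] = []
        freq: Dict[str, int] = {n: 0 for n in names}
        for m in range(self.n_models):
            seed_m = ens_seed + m
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=self.subsample, stratify=y,
                random_state=seed_m)
            rf = RandomForestClassifier(
                n_estimators=n_est, max_features=mf,
                random_state=seed_m, n_jobs=1)
            rf.fit(X_tr, y_tr)
            imp = rf.feature_importances_
            # stable sort over lexicographic name order breaks importance
            # ties by feature name
            ranked = lex_order[np.argsort(-imp[lex_order], kind="stable")]
            cut = imp[ranked[self.top_n - 1]]
            n_at_cut = int((imp == cut).sum())
            if n_at_cut > 1 and (imp[ranked[: self.top_n]] == cut).sum() < n_at_cut:
                logger.info("model %d: importance tie at rank %d broken "
                            "lexicographically", m, self.top_n)
            top = [names[i] for i in ranked[: self.top_n]]
            per_model_top.append(top)
            for nme in top:
                freq[nme] += 1
            accuracies.append(float(rf.score(X_te, y_te)))

        self.per_model_top_ = per_model_top
        self.frequencies_ = freq
        self.per_model_accuracy_ = accuracies
        self.mean_accuracy_ = float(np.mean(accuracies))
        self.ci_low_, self.ci_high_ = bootstrap_ci(
            accuracies, n_boot=self.n_bootstrap, level=self.ci_level,
            seed=boot_seed)
        self.panel_ = select_balanced(freq, self.balanced_threshold)
        in_panel = set(self.panel_.probes)
        self.support_ = np.asarray([n in in_panel for n in names])
        self.feature_names_in_ = name_arr
        self.n_features_in_ = n_features
        logger.info(
            "stability selection: %d/%d models done, mean accuracy %.4f "
            "(%.0f%% CI %.4f-%.4f), %d balanced markers",
            self.n_models, self.n_models, self.mean_accuracy_,
            100 * self.ci_level, self.ci_low_, self.ci_high_,
            len(self.panel_))
        return self

    def get_support(self):
        return self.support_

    def result(self) -> StabilityResult:
        return StabilityResult(
            per_model_top=self.per_model_top_,
            frequency=self.frequencies_,
            per_model_accuracy=self.per_model_accuracy_,
            mean_accuracy=self.mean_accuracy_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            tuned_params=self.tuned_params_,
            threshold=self.balanced_threshold,
        )


def run_ensemble(train: ExpressionMatrix, candidates: Sequence[str],
                 cfg: PipelineConfig, tune: bool = True,
                 tuning_grid: Optional[dict] = None) -> StabilityResult:
    """Matrix-level wrapper: run stability selection on candidate probes."""
    X, y, names = train.to_xy(probes=list(candidates))
    sel = StabilitySelector(
        n_models=cfg.n_models, subsample=cfg.model_subsample,
        top_n=cfg.top_n_rank, balanced_threshold=cfg.balanced_threshold,
        cv_folds=cfg.cv_folds, n_bootstrap=cfg.n_bootstrap,
        ci_level=cfg.ci_level, tune=tune, tuning_grid=tuning_grid,
        random_state=cfg.seed,
    )
    sel.fit(X, y, feature_names=names)
    return sel.result()
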
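"""Synthetic multi-cancer serum-miRNA cohort generator with planted markers.

The generator emulates the statistical structure the discovery pipeline
assumes: log-scale intensities with per-probe baselines, additive +
multiplicative batch effects across a few pseudo-batches, negative-control
probes that define the presence threshold, and a handful of planted
markers -- pan-cancer (shifted in every cancer sample) or type-specific
(shifted only in one cancer type) -- among null probes.

Variance bookkeeping for the Gaussian-shift AUC oracle: with batch
effects disabled (``batch_shift_sd = batch_scale_sd = 0``) the values of a
pan marker are N(b_m, within_sd) in controls and N(b_m +/- delta,
within_sd) in cancers -- the baseline b_m is a per-probe constant and
contributes no between-sample variance -- so the single-probe AUC is
exactly Phi(delta / (within_sd * sqrt(2))), the equal-variance Gaussian
two-sample form.  With batch effects on, batch membership is independent
of class, inflating the within-group SD and attenuating the realized AUC
until normalization removes the batch component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Set

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SyntheticConfig
from .matrix import CLASS_CANCER, CLASS_NON_CANCER, NO_TYPE, ExpressionMatrix

logger = logging.getLogger(__name__)

#: reserved probe-id prefix marking negative-control probes
NEG_CONTROL_PREFIX = "NEGCTRL"


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: which probes are planted markers."""

    pan_marker_ids: Set[str] = field(default_factory=set)
    type_marker_ids: Dict[str, str] = field(default_factory=dict)
    direction: Dict[str, str] = field(default_factory=dict)  # probe -> up/down
    effect_delta: float = 0.0

    def __post_init__(self):
        overlap = self.pan_marker_ids & set(self.type_marker_ids)
        if overlap:
            raise ValueError(f"probes planted as both pan and type markers: {overlap}")

    @property
    def marker_ids(self) -> Set[str]:
        return self.pan_marker_ids | set(self.type_marker_ids)


def theoretical_auc(delta: float, sigma: float) -> float:
    """Closed-form AUC of a single Gaussian-shift marker.

    For scores N(mu, sigma^2) in controls and N(mu + delta, sigma^2) in
    cases, P(case score > control score) = Phi(delta / (sigma * sqrt(2))).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(norm.cdf(delta / (sigma * np.sqrt(2.0))))


def generate_cohort(cfg: SyntheticConfig):
    """Generate one cohort; returns ``(ExpressionMatrix, SyntheticTruth)``.

    Deterministic: equal configs (including seed) yield bit-identical
    matrices.
    """
    if not cfg.per_type_counts:
        raise ValueError("per_type_counts is empty")
    if cfg.n_controls == 0:
        warnings.warn(
            "cohort has no non-cancer controls; the two-class pipeline "
            "downstream will fail",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)

    types = list(cfg.per_type_counts)
    sample_ids, labels, ctypes = [], [], []
    for t in types:
        n_t = cfg.per_type_counts[t]
        sample_ids += [f"{t}_{i:04d}" for i in range(n_t)]
        labels += [CLASS_CANCER] * n_t
        ctypes += [t] * n_t
    sample_ids += [f"control_{i:04d}" for i in range(cfg.n_controls)]
    labels += [CLASS_NON_CANCER] * cfg.n_controls
    ctypes += [NO_TYPE] * cfg.n_controls
    n_samples = len(sample_ids)

    width = max(4, len(str(cfg.n_probes)))
    probe_ids = [f"miR-SYN-{i:0{width}d}" for i in range(cfg.n_probes)]

    # planted markers: disjoint random probe subsets, random sign each
    chosen = rng.choice(cfg.n_probes, size=cfg.n_pan_markers + cfg.n_type_markers,
                        replace=False)
    pan_idx = chosen[: cfg.n_pan_markers]
    type_idx = chosen[cfg.n_pan_markers:]
    signs = rng.choice([1.0, -1.0], size=len(chosen))
    truth = SyntheticTruth(effect_delta=cfg.effect_delta)
    truth.pan_marker_ids = {probe_ids[i] for i in pan_idx}
    for j, i in enumerate(type_idx):
        truth.type_marker_ids[probe_ids[i]] = types[j % len(types)]
    for j, i in enumerate(chosen):
        truth.direction[probe_ids[i]] = "up" if signs[j] > 0 else "down"

    # batch structure: membership independent of class
    batches = rng.integers(0, cfg.n_batches, size=n_samples)
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_batches)
    batch_scale = np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=cfg.n_batches))

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_probes)
    # planted markers emulate confidently detected miRNAs: their baselines
    # sit in the upper half of the baseline distribution so that a downward
    # class shift cannot push them below the presence threshold -- ground
    # truth should be recoverable through the planted effect, not lost to
    # detectability
    baseline[chosen] = cfg.baseline_mean + np.abs(baseline[chosen]
                                                  - cfg.baseline_mean)
    values = baseline[:, None] + rng.normal(
        0.0, cfg.within_sd, size=(cfg.n_probes, n_samples)
    )

    is_cancer = np.asarray([lab == CLASS_CANCER for lab in labels])
    ctype_arr = np.asarray(ctypes)
    for j, i in enumerate(pan_idx):
        values[i, is_cancer] += signs[j] * cfg.effect_delta
    for j, i in enumerate(type_idx):
        mask = ctype_arr == types[j % len(types)]
        values[i, mask] += signs[cfg.n_pan_markers + j] * cfg.effect_delta

    # negative-control probes: flat low signal, no class effect
    neg_ids = [f"{NEG_CONTROL_PREFIX}-{i:03d}" for i in range(cfg.n_neg_controls)]
    neg_values = rng.normal(cfg.neg_mean, cfg.neg_sd,
                            size=(cfg.n_neg_controls, n_samples))

    all_values = np.vstack([values, neg_values]) if cfg.n_neg_controls else values
    all_values = (all_values * batch_scale[batches][None, :]
                  + batch_shift[batches][None, :])

    frame = pd.DataFrame(all_values, index=probe_ids + neg_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"label": labels, "cancer_type": ctypes,
         "batch": [f"batch{b}" for b in batches]},
        index=sample_ids,
    )
    logger.info(
        "generated cohort: %d probes (+%d negative controls) x %d samples, "
        "%d pan / %d type markers, delta=%.3g, seed=%d",
        cfg.n_probes, cfg.n_neg_controls, n_samples,
        cfg.n_pan_markers, cfg.n_type_markers, cfg.effect_delta, cfg.seed,
    )
    return ExpressionMatrix(frame, samples), truth
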
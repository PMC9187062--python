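"""Run configuration objects: pipeline constants, split plan, generator profile."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict

from . import reference


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (0.5 -> 1, 1.5 -> 2).

    A tiny epsilon guards against products like 345 * 0.7 landing one ulp
    below an exact half.
    """
    return int(math.floor(x + 0.5 + 1e-9))


@dataclass
class SplitPlan:
    """Per-type training fractions for the stratified train/validation split.

    ``fraction_by_type`` maps each cancer type to its training fraction;
    ``non_cancer_fraction`` governs the controls.  Defaults reproduce the
    reference cohort's plan: 40% of prostate, 70% of ovarian / bladder /
    hepatocellular, 80% of every other type, and ~80% of controls so the
    overall training share is ~73%.
    """

    fraction_by_type: Dict[str, float] = field(
        default_factory=lambda: dict(reference.TRAINING_FRACTIONS)
    )
    non_cancer_fraction: float = reference.NON_CANCER_TRAINING_FRACTION
    seed: int = 0

    def __post_init__(self):
        for t, f in self.fraction_by_type.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"training fraction for {t!r} must be in (0,1): {f}")
        if not 0.0 < self.non_cancer_fraction < 1.0:
            raise ValueError("non_cancer_fraction must be in (0,1)")


@dataclass
class PipelineConfig:
    """Constants of the marker-discovery pipeline.

    The defaults are the procedure's canonical settings: top 500 miRNAs by
    FDR enter stability selection; 100 random forest models each trained on
    a stratified 80% subsample; the top 10 probes per model by mean decrease
    in Gini are tallied; probes appearing in >= 90 of the model top-10 lists
    are "balanced"; forest hyperparameters tuned by 10-fold CV; a 10,000
    replicate bootstrap gives the 95% CI on mean model accuracy.
    """

    k_top: int = 500
    n_models: int = 100
    model_subsample: float = 0.8
    top_n_rank: int = 10
    balanced_threshold: int = 90
    cv_folds: int = 10
    n_bootstrap: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    split_plan: SplitPlan = field(default_factory=SplitPlan)

    def __post_init__(self):
        for name in ("k_top", "n_models", "top_n_rank", "balanced_threshold",
                     "cv_folds", "n_bootstrap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("model_subsample", "ci_level"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0,1)")
        if self.balanced_threshold > self.n_models:
            raise ValueError("balanced_threshold cannot exceed n_models")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticConfig:
    """Profile of a simulated multi-batch, multi-cancer serum miRNA cohort.

    The simulated measurement for probe m in sample s is, on the log scale,

        x_ms = d_b + s_b * (b_m + effect_ms + eps),   eps ~ N(0, within_sd)

    with per-probe baseline b_m ~ N(baseline_mean, baseline_sd), additive
    batch offset d_b ~ N(0, batch_shift_sd) and multiplicative batch scale
    s_b = exp(N(0, batch_scale_sd)).  Pan-cancer markers carry a location
    effect of +/- effect_delta in every cancer sample; type-specific markers
    only in samples of their type.  Negative-control probes (reserved id
    prefix) carry N(neg_mean, neg_sd) in place of b_m and no class effect.

    The default effect size delta=2.5 at within_sd=1 gives planted pan
    markers a theoretical single-probe AUC of ~0.96, comparable to the
    per-miRNA discrimination of real pan-cancer serum markers.
    """

    n_probes: int = 2500
    n_pan_markers: int = 5
    n_type_markers: int = 13
    per_type_counts: Dict[str, int] = field(
        default_factory=lambda: dict(reference.COHORT_COUNTS)
    )
    n_controls: int = 2809
    effect_delta: float = 2.5
    within_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_batches: int = 4
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.05
    n_neg_controls: int = 20
    neg_mean: float = 4.0
    neg_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_pan_markers + self.n_type_markers > self.n_probes:
            raise ValueError("more planted markers than probes")
        for name in ("n_probes", "n_pan_markers", "n_type_markers", "n_controls",
                     "n_batches", "n_neg_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        if not self.per_type_counts:
            raise ValueError("per_type_counts must name at least one cancer type")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Small profile for fast runs: reference cohort scaled to ~200 cancer
        + 200 control samples, 300 probes, 5 pan markers, no type markers."""
        counts = {
            t: max(2, round_half_up(n * 0.06))
            for t, n in reference.COHORT_COUNTS.items()
        }
        defaults = dict(
            n_probes=300,
            n_pan_markers=5,
            n_type_markers=0,
            per_type_counts=counts,
            n_controls=200,
            n_neg_controls=10,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def n_cancer(self) -> int:
        return sum(self.per_type_counts.values())
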
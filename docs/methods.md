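# Methods

## The discovery procedure

`mirpanel` treats pan-cancer marker discovery as a stability-selection
problem. All cancer types are pooled into one "cancer" class against
non-cancer controls; a marker is useful for general screening only if it
keeps its discriminative rank under resampling of the training cohort.
Concretely, after preprocessing and a Welch/FDR prefilter to the 500
candidate miRNAs with smallest q-values, `n_models` (canonically 100)
random forest classifiers are each trained on an independent
class-stratified `subsample` (80%) of the training set. In each model the
candidates are ranked by mean decrease in Gini — the impurity reduction a
feature contributes, weighted by the probability of reaching its split
nodes — and the `top_n` (10) best are recorded along with the model's
accuracy on its held-out 20%. A miRNA appearing in at least
`balanced_threshold` (90) of the per-model top-10 lists is *balanced*; the
threshold is inclusive, so a frequency of exactly 90 of 100 qualifies.
The uncertainty of the mean held-out accuracy is summarized by a
percentile bootstrap over the per-model accuracies (10,000 replicates,
95% interval).

The random forest itself is the scikit-learn implementation; the package's
contribution is the ensemble-frequency procedure around it, which only
requires a seedable classifier exposing an impurity-based importance
vector. Forest hyperparameters (features per split in {√m, m/3, log₂m},
trees in {250, 500, 1000}; everything else at library defaults) are chosen
by stratified 10-fold CV accuracy, ties broken by grid order so the choice
is deterministic.

Balanced markers are then evaluated by per-miRNA ROC/AUC on training and
validation sets and by an exhaustive logistic-combination search: every
non-empty subset of the panel is fitted (binomial logistic regression —
with two classes the multinomial model reduces to the binomial one — with
a small ridge penalty, λ ≈ 1/n i.e. `C = n_samples`, so complete
separation cannot break the fit), the winner maximizes *training* AUC with
ties broken by smaller subset then lexicographic order, and only the
winner is scored on the validation set. Selecting on training AUC alone
avoids validation leakage; the alternative (selecting on validation AUC)
would bias the reported validation metrics upward. Classification metrics
(accuracy, sensitivity, specificity) are computed at a fixed probability
threshold of 0.5; the procedure has no natural threshold choice, and 0.5
is the symmetric default. Sample structure over the panel is visualized by
agglomerative clustering with complete linkage and Euclidean distance,
whose 2-cluster cut is compared to the class labels by adjusted Rand
index.

## Preprocessing

* **Presence call.** Per sample, threshold T = mean + 2·SD (sample SD,
  ddof = 1) over that sample's negative-control probes; signals strictly
  above T are kept and background-subtracted by the control mean, others
  become absent. Retained values are therefore never negative. The
  subtraction also cancels any additive per-sample (batch) offset, since
  controls and signals share it.
* **Absence policy.** Probes absent in more than 50% of samples are
  dropped; remaining absences are set to 0 before normalization. The
  procedure needs a dense matrix here and this mirrors common microarray
  practice; the cutoff is exposed as `max_absent_frac`.
* **Quantile normalization.** Classical cross-sample rank-mean
  normalization: every sample's sorted vector is replaced by the
  across-sample mean of sorted vectors; tied values receive the mean of
  the reference quantiles they span (the sorted-equality invariant then
  holds exactly for tie-free data). Implemented as a fit/transform
  estimator so a reference learned on training samples can be applied to
  new ones.
* **Stratified split.** Per cancer type t, round-half-up(n_t · f_t)
  samples are drawn uniformly without replacement into training. Default
  fractions: prostate 0.40; ovarian, bladder, hepatocellular 0.70; all
  other types 0.80; non-cancer 0.7997 (chosen so the overall training
  share of the reference cohort is ≈ 73%). On the reference cohort
  profile this yields 2252 cancer training samples (prostate 324, ovarian
  224, bladder 274, hepatocellular 242, remaining types 1188); the
  published accounting for the same cohort prints 2253, a one-sample
  discrepancy that no single rounding rule reproduces (the printed train
  + validation totals also exceed the printed overall total by 3), so the
  package fixes round-half-up and writes a split manifest that makes its
  own integerization auditable.
* **Deduplication.** Cohorts assembled from overlapping batches keep the
  first occurrence of each sample id in input order; conflicting
  duplicate values are logged. No probe harmonization is attempted.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not real miRNA biology. On the log-intensity scale,

    x_ms = d_b + s_b · (b_m + effect_ms + ε),   ε ~ N(0, σ_w²)

with per-probe baseline b_m ~ N(8, 1.5²) (arbitrary log-intensity units),
additive batch offset d_b ~ N(0, 0.3²) and multiplicative scale
s_b = exp(N(0, 0.05²)) across 4 pseudo-batches with class-independent
membership — exactly the artifact class quantile normalization removes.
Pan-cancer markers are shifted by ±δ in every cancer sample,
type-specific markers only in their type; the sign is random so selection
cannot exploit direction (real balanced panels contain both over- and
under-expressed markers). Negative-control probes (reserved id prefix
`NEGCTRL`) carry N(4, 0.5²) in place of b_m and define the presence
threshold. Planted-marker baselines are drawn from the upper half of the
baseline distribution so that a downward shift cannot push a marker below
the detection floor: ground truth should be recoverable through the
planted effect, not lost to detectability.

Variance bookkeeping: baselines are per-probe constants, so with batch
effects off the within-group SD of a probe is exactly σ_w and the
single-marker AUC is Φ(δ/(σ_w√2)) (`theoretical_auc`). With batch
effects on, batch membership inflates the within-group variance and
attenuates the realized AUC until normalization removes the batch
component.

Defaults: the full profile mirrors the reference cohort (13 types, 3352
cancer + 2809 controls, 2500 probes); `SyntheticConfig.desk_scale()`
scales the type counts by 0.06 (≈ 200 cancer + 200 controls, 300 probes,
5 pan markers) for runs that finish in minutes on one core. δ = 2.5 at
σ_w = 1 gives planted markers a theoretical AUC ≈ 0.96, comparable to the
per-miRNA discrimination reported for real pan-cancer serum markers.
What passing tests on this generator demonstrate: the pipeline recovers
location-shifted markers of realistic effect size from Gaussian log-scale
noise with batch structure. What they do not demonstrate: robustness to
heavy-tailed intensity distributions, correlated probe blocks,
platform-specific saturation, or markers whose effect varies by cancer
type — real-data performance claims require real cohorts.

## Network tools

MCODE-style clustering follows the standard three phases: (1) each vertex
with degree ≥ `degree_cutoff` is weighted by k·density of the highest
k-core of its closed neighborhood (others weigh 0); (2) clusters grow
from the highest-weight unassigned seed, admitting neighbors whose weight
is ≥ seed weight · (1 − `node_score_cutoff`), to at most `max_depth`
hops; (3) candidates lacking a k-core are discarded, the rest score
density × size, and clusters scoring ≥ `min_cluster_score` are reported.
A clique of n nodes scores exactly n, which the tests exploit. The
conventional node score cutoff is a fraction in (0,1); the package uses
0.2. Haircut and fluff post-processing are omitted. The score threshold
is inclusive (≥ 5). Enrichment uses the upper-tail hypergeometric
p = P(X ≥ k) with pathway sets intersected with the user-supplied
universe and BH adjustment across pathways. No interaction or pathway
databases ship with the package; analyses run on user-supplied edge
tables and GMT files.

## Numerical and design choices

* All randomness flows from a single integer seed; internally
  `numpy.random.SeedSequence` spawns independent child streams for
  tuning, ensemble subsampling and the bootstrap, so equal seeds give
  bit-identical frequency tables, splits and intervals.
* Welch's t is computed vectorized across probes with the
  Welch–Satterthwaite df; degenerate zero-variance cases are defined
  (equal means → t = 0, p = 1; unequal → p = 0) rather than NaN.
  scipy's implementation serves as an independent oracle in tests.
* FDR means Benjamini–Hochberg step-up (the default meaning in this
  literature); candidate ranking ties break by (q, p, probe id) so the
  top-500 is reproducible.
* Importance ties at the top-10 boundary break lexicographically by
  probe id and are logged.
* Bootstrap CI is the percentile method; fewer than 100 replicates warns.
* `round_half_up` carries a 1e-9 epsilon so products like 345·0.7 do not
  land one ulp below an exact half.
* The exhaustive combination search refuses panels larger than 15
  (2¹⁵ subsets) as a combinatorial guard.
* Reported study sizes (desk profile, 20-model ensembles in examples and
  the reproduction script) were chosen so a complete study is
  statistically meaningful yet finishes in minutes on a single core.

## Known limitations

* Only class/type/batch annotations are modeled; age, sex and stage are
  not represented in the series-matrix dialect.
* The multi-class structure is used only for stratification; selection is
  strictly cancer vs non-cancer (no per-type one-vs-rest selection, no
  per-type sensitivity breakdown).
* Quantile normalization is the only batch-correction step, matching the
  reference procedure; confounded batch–class designs are out of scope.
* The Gaussian-on-log-scale noise model is an assumption of the
  generator, not a validated property of serum miRNA arrays.
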
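# Methods

## Connectome features

Each subject is a T × R matrix of preprocessed ROI time series (the package
starts after standard fMRI preprocessing; slice timing, motion correction,
normalisation, nuisance regression and band-pass filtering are out of
scope). Functional connectivity between ROIs i and j is the Pearson
correlation of their time series; values are mapped through Fisher's
r-to-z transform, z = ½ ln((1+r)/(1−r)), with |r| clipped to 1 − 1e−7 first
so the transform stays finite on degenerate (perfectly correlated) series.
The feature vector is the strict upper triangle of the R × R matrix in
row-major pair order (0,1), (0,2), …, (R−2,R−1); this ordering is fixed,
written into every output file, and invertible (`fold_upper_triangle`).
ROIs are indexed 0-based internally; all human-readable outputs use ROI
names (`<roiA>--<roiB>` for connections). Zero-variance ROI series and NaNs
are hard errors naming the offending column, not silent repairs.

## All-relevant selection

The selection loop follows the shadow-feature ("Boruta") scheme:

1. Every active feature column is independently permuted across subjects to
   form a shadow copy (fresh permutations each iteration — hits must be
   independent trials).
2. A random forest (default 500 trees; Gini impurity; √p feature
   subsampling; bootstrap) is fit to [real | shadow] and per-feature Gini
   importances extracted. Tree fitting is delegated to
   sklearn's RandomForestClassifier; the contract here is the importance
   semantics, not the forest implementation.
3. A real feature scores a hit when its importance strictly exceeds the
   95th percentile (linear interpolation between order statistics) of the
   shadow importances.
4. After t iterations a feature with h hits is tested against
   Binomial(t, p₀): exact upper tail P(X ≥ h) to confirm, exact lower tail
   P(X ≤ h) to reject. Within each iteration the tests across the
   still-undecided family receive a two-step correction — Benjamini–
   Hochberg across the family *and* Bonferroni at α divided by the active
   feature count; a feature changes state only when both corrected tests
   are significant. The conjunction matters: a lone BH step across the
   family that remains late in the run is liberal enough to confirm
   chance correlates (see limitations).
5. Rejected features are removed from the working matrix at the iteration
   they are rejected; the loop ends when nothing is undecided or after
   `max_iter` (default 250) iterations, and survivors are reported
   *tentative*. Only confirmed features are passed to classification by
   default (`include_tentative` flips this).

The binomial null p₀ defaults to 0.5 — the hit/no-hit coin of the reference
two-step scheme — with 0.05 selectable: the published phrase "binomial
distribution with p = 0.05" admits both readings (null probability vs
significance level), and we treat 0.05 as the significance level α.
`correction` can also be set to `bonferroni_only` or `none` for audit.
All randomness flows from a single seed; two runs with the same seed give
bit-identical decisions, hit counts and importance histories.

## Classification

An RBF-kernel SVM (C = 1, γ = 1/(p·var) — the library's "scale" rule; the
source analysis states no hyperparameters, so the library defaults are used
and echoed into every report) is evaluated by leave-one-out
cross-validation: n folds, each fit on n−1 subjects and predicting the
held-out one. Features are z-scored per connection using training-fold
statistics only, applied to the held-out subject — standardisation before
the split would leak the test subject's scale.

An RBF machine has no primal weight vector, yet connection-level weights
are the object of interest; the per-fold weight is the standard
pseudo-primal surrogate w = Σᵢ αᵢyᵢxᵢ over support vectors (exact primal
when `kernel="linear"`, which is provided for exact-weight audits). Mean
weights across folds are the classification weights used downstream.
Patients are the positive class (+1) everywhere: sensitivity is the
fraction of patients predicted positive, specificity the fraction of
controls predicted negative, reported as percentages to one decimal.

Significance of the observed accuracy comes from a permutation test: labels
are redrawn uniformly, the full LOOCV is rerun, and
p = (1 + #{null ≥ observed}) / (n_perm + 1) (the add-one form avoids p = 0).
`selection_mode="once"` (default) runs selection once on all subjects and
permutes only the classifier — this mirrors the source analysis but leaks
selection information into the folds; `selection_mode="nested"` reruns
selection inside every permutation for a leakage-free null at much higher
cost. Reports label which mode produced them.

## Interpretation analytics

* Region weight: sum of |w| over connections incident to the region
  (absolute mode default — the aggregate is used as a magnitude ranking;
  `signed` mode is kept for audit). Conservation: Σ region weights =
  2 Σ |connection weights|.
* Network weight: sum of member region weights (partitions the region
  total exactly).
* Important regions: weight strictly greater than mean + 2 SD of the
  *contributing* regions (those incident to at least one selected
  connection), sample (n−1) SD; ties at the threshold are excluded.
  Note the rule can only fire with ≥ 6 contributing regions: the largest
  standardised deviation in a sample of n is (n−1)/√n, which first exceeds
  2 at n = 6.
* Network degree ND(N): number of selected connections with exactly one
  endpoint in N; Σ ND = 2 × (between-network connection count).
* Patterns: k-means (Lloyd, k-means++ seeding, best of 100 restarts, via
  sklearn's KMeans) on the connections × subjects profile matrix, all
  subjects as columns. Default k = 3 (the analysis this package
  operationalises reports three patterns without stating how k was
  chosen); a silhouette scan over k = 2..8 is emitted alongside so the
  choice is inspectable.

## Clinical association

The per-subject, per-connection classification score is defined as
mean weight × standardised feature value — the connection's additive
contribution to the (pseudo-primal) decision value. The source analysis
never defines its "classification score"; this definition is the one that
ties the score to the classifier while still varying across subjects, and
it is stated prominently because other readings (raw FC, weighted raw FC)
are possible. Scores are Pearson-correlated with the five symptom scales in
patients only, two-sided p from the t-distribution with n−2 df, pairwise
deletion of missing scale values, pairs with fewer than 3 complete
observations or constant vectors reported as undefined rather than dropped.
No multiplicity correction by default (the analogous published table
reports uncorrected p-values); a BH option exists because
connections × scales is a large family.

## Synthetic data

The generator emulates the study conditions: 48 patients vs 50 controls;
a six-network atlas with block sizes proportional to the 160-ROI functional
atlas (34/21/32/33/22/18 for DMN/FPN/CON/SMN/ON/CN); T = 170 timepoints
(180 acquired volumes minus 10 discarded); 125 planted discriminative
connections by default.

Feature-level path (primary, fast): each connection value = baseline
(0.50 within-network, 0.15 between — typical Fisher-z levels — plus fixed
per-connection jitter) + a per-subject network-pair latent (SD 0.10,
inducing the within-block feature correlation real connectomes show) +
independent noise (SD 0.25, approximating between-subject variability of
z-scale FC) + for patients, ±d·σ on planted connections (σ the within-group
SD, so d is Cohen's d; hyper-/hypo-connectivity signs random per
connection). Time-series path (integration): ROI signal = AR(1) network
latent × 0.55 + pair-specific shared components on planted connections with
group-dependent mixing + unit white noise; running the real connectome
pipeline on these series reproduces elevated within-network FC and the
planted group differences. Patient scales are affine maps of a standardised
combination of the clinical-linked connections, calibrated to the cohort's
published scale means/SDs (e.g. ADOS total 11.71 ± 4.28, range 0–24),
integer-rounded and clipped by default.

What the generator does *not* emulate: hemodynamics, motion and scanner
artefacts, site effects, heavy-tailed FC distributions, realistic
inter-connection correlation beyond the block latent. Passing tests
therefore show the pipeline recovers the structure it assumes, at the
stated effect sizes — not that comparable accuracy is attainable on real
cohorts, where published headline numbers live on data this package does
not download.

Validation sizes: tests and the acceptance script run the selection on
98 subjects × 300 features (20 planted at d = 1.5, 100 trees, ≤ 50
iterations) and the end-to-end analysis on a 40-ROI atlas (780
connections); these keep full-pipeline checks to minutes while preserving
the n ≪ p regime that drives the method's behaviour.

## Known limitations

* **All-relevant selection is not null-calibrated at small n.** On pure
  noise with n = 98 and 300 features, the largest chance sample
  correlations (|r| ≈ 0.30–0.36) are *fixed* attributes of the sample:
  such features beat the shadow 95th percentile persistently, accumulate
  hits far above the binomial-null rate, and are confirmed — by this
  implementation and equally by a line-faithful replica of the reference
  decision scheme, at either the 95th-percentile or the shadow-max hit
  rule. Expect a handful of confirmed features from pure noise at this
  sample size (the effect shrinks as rejection thins the shadow family's
  protection, and grows with `max_iter`). With genuine signal present the
  forest concentrates on real features and the measured false-confirmation
  rate drops well below 1%. Consequence: a nonempty confirmed set on its
  own is weak evidence of signal; the permutation test of the downstream
  classifier, not the selection count, carries the inferential weight.
* Selection run once on all subjects before LOOCV (the default,
  source-faithful mode) biases LOOCV accuracy upward; use
  `selection_mode="nested"` for honest error estimates.
* The pseudo-primal weights of an RBF machine are a linearisation; rankings
  built on them should be read as heuristics unless the linear kernel
  reproduces them.
* Permutation p-values are Monte-Carlo with floor 1/(n_perm+1); report the
  floor, not "p = 0".
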
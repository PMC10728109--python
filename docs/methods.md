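# Methods

## The model

`ewsdda` analyses a positive feature-by-sample matrix (gene expression or
metabolite concentrations) whose samples carry an *ordered* class label:
disease stages (normal, I–IV) in a cross-sectional design, or time points
(T1…T7) in a paired longitudinal design.  The unit of analysis is not a
feature but a **molecular ratio** r_ij = f_i / f_j, read as the outcome of
an assumed pathway reaction converting one molecule into the other; a
shift in a ratio indicates a change in the activity of that reaction.

For every canonical pair (i < j in feature-list order) and every class c_k
the package computes a shrunken-centroid statistic

    d_ijk = (mu_ijk − mu_ij) / (m_k · (s_ij + s_0))

where mu_ijk is the class-k mean of the ratio, mu_ij its grand mean,
s_ij the pooled within-class SD with the unbiased n − z denominator
(z = number of classes), s_0 the median of s_ij over all ratios (a
stabiliser that damps ratios with small raw scale), and
m_k = sqrt(1/n + 1/n_k) by default.  The classical nearest-shrunken-
centroid factor sqrt(1/n_k − 1/n) — the exact standard error multiplier
for a class mean versus the grand mean — is available as
`mk_form="classical"`; the default is the former because that is the
convention this pipeline follows, and every property of the pipeline holds
under either form.  d_ijk is a t-like contrast of class k against the
cohort centroid.

**Dynamic networks.**  For each class, features f_i and f_j are linked
when |d_ijk| ≥ ε, with sign "up" (red) for d ≥ ε and "down" (green) for
d ≤ −ε; thresholds are inclusive.  Conventional defaults are ε = 0.6 for
staged designs and ε = 2.3 for time-series designs; edge sets are nested
in ε by construction.

**Early-warning subnetwork.**  The focus-class graph (earliest disease
stage, or the onset time point) is ranked by node degree, descending, ties
broken deterministically by feature-list order.  The top-k nodes (k = 5
for staged, k = 1 for longitudinal analyses by default) plus their first
neighbors form the crucial subnetwork; the ratios on hub-incident edges
are the candidate biomarkers.

**Selection funnels.**  Staged: a candidate survives if (a) the early
stage differs significantly (two-sample t, Welch by default, raw p < α,
α = 0.05) from at least 2 of the 3 later stages, (b) *every* disease stage
differs from the reference class, and (c) its per-stage mean trajectory is
strictly monotone.  Longitudinal: (a) model vs control arm significant at
every disease time point (unpaired — the arms have different numbers of
subjects), (b) subject-paired t-tests between the last pre-onset time
point and every disease time point all significant, and (c) an
onset-persistent trajectory.  No multiple-testing correction is applied by
default (raw p < 0.05 is the convention here); every funnel stage logs its
survivor count.

**Trajectory rules.**  `strict_monotone` requires strictly increasing or
strictly decreasing class means.  `onset_persistent` requires pre-onset
means within a band around the first class's mean and all post-onset means
outside the band on one common side.  The band half-width is
3·sqrt(2)·(rms pre-onset SE): the difference of two class means has SE
≈ sqrt(2) times a single mean's SE, and a ±1-SE band would reject a
genuinely stable pre-onset trajectory about half the time per comparison;
the 3-sigma gate keeps stable trajectories inside the band with ~99%
probability per comparison while a shift of a few within-class SDs clears
it decisively.

**Evaluation.**  Panel ROC: unpenalised binary logistic regression on the
panel ratios (on perfect separation, the unpenalised least-squares linear
combination is used instead — AUC is rank-based and unaffected); AUC by the
Mann–Whitney rank formulation with half credit for ties; SE by the
Hanley–McNeil formula; 95% CI = AUC ± 1.96·SE clipped to [0, 1]; "best"
cutoff maximises Youden's J with ties broken toward higher sensitivity.
PCA autoscales columns (centre, unit variance — the metabolomics-profiling
default; `scale=False` gives centring only) and drops zero-variance
columns.  Survival: multivariate Cox proportional hazards (Breslow ties),
risk score = linear predictor, rank-based median split into high/low
groups (sizes differ by ≤ 1; ties at the threshold resolved by sample
order), two-group log-rank test, and Kaplan–Meier curves serialised as
step functions.  With no events in a group the log-rank result is reported
as undefined rather than a number.

## Synthetic data generator

The generator exists so every downstream stage is testable without the
original cohorts.  Features are log-normal, log f = b_f + e with
b_f ~ N(3, 0.5²) and e ~ N(0, noise_sd²), noise_sd = 0.3 by default:
positivity is guaranteed and effects are SD-interpretable.  The staged
default is study-scale: 90 features and unequal stage sizes
(50/171/86/85/5).  The longitudinal default is 7 model and 10 control
subjects at 7 time points (49 + 70 samples), onset at T5.

**Planted signals are coupled pairs, not mean shifts.**  A signal is a hub
plus partners; each partner is generated from the hub with a fixed log
offset and small coupling noise (ratio_sd = noise_sd/60), so the
hub/partner log-ratio is a tight pathway readout whose pooled SD is
ratio_sd.  The planted shift moves that log-ratio by
effect_size × ratio_sd, with a stage profile:

* staged, persistent=False — the shift applies at the signal class only;
* staged, persistent=True — the shift grows stepwise,
  effect_size × (stage − onset + 1) SDs, the shape required by the staged
  funnel itself (a flat persistent shift cannot satisfy the
  early-vs-later-stage significance rule or a monotone trajectory);
* time-series — a flat plateau from onset onward (stable high expression
  after disease onset).

Coupling is a *necessity*, not a convenience: a ratio shift is the
difference of two per-feature log shifts, so any scheme that moves feature
means leaks shifts of comparable size into every partner-versus-background
ratio, which both destroys the hub's degree dominance and floods the panel
with false positives.  Tight coupling confines the differential signal to
the hub–partner ratios (partner–partner ratios cancel exactly).

**Raw-scale calibration.**  Because d works on raw ratios, its response to
a fixed log shift depends on the ratio's raw scale relative to s_0.  Two
structural facts shape the detectable window:

* the grand-mean centring spreads a one-class shift into the other classes
  at −n_k/(n − n_k) of the signal-class numerator (−1/4 with five equal
  classes), so the signal-class d must stay below ~4ε or planted edges
  appear at other stages;
* the s_0 stabiliser caps the one-class d at 16·u at effect size 4, where
  u = s_planted/(s_planted + s_0).

The generator therefore places the planted ratio's raw scale at
X × (predicted median ratio SD)/ratio_sd with X = 0.08 (staged), putting
the signal-class d near 16X/(1+X) ≈ 1.2 — comfortably above ε = 0.6 with
the spillover near 0.3, below it.  The time-series plateau dilutes the
onset contrast to (1 − 3/7) of the shift and must clear ε = 2.3, hence
X = 1.5 there (onset d ≈ 3.4, pre-onset spillover ≈ −2.5: pre-onset edges
are green, post-onset red — the topology-flip signature the longitudinal
analysis looks for).  The predicted median accounts for the design's
composition: when the coupled motif ratios hold the median rank the
predicted s_0 is sqrt(2)·ratio_sd, otherwise the background median is
shifted to the appropriate quantile of the baseline-scale distribution.
These constants were fixed by a design-phase simulation study before the
test suite was frozen.

**What the generator does not emulate**: pathway structure beyond the
planted motif, correlated background features, LC–MS peak artefacts,
batch effects, within-subject autocorrelation in the longitudinal design,
and heavy-tailed measurement error.  Passing tests demonstrate that the
implementation recovers the signals it defines under its own noise model —
not that the method would behave identically on real cohorts.

## Recovery-experiment design

The planted-recovery experiments (hub-top-degree, edge specificity, final
panel) run on motif-only cohorts: 6 features (hub first, then 5 partners),
n_k = 30 per stage.  This is deliberate.  At ε = 0.6 the null exceedance
P(|d| ≥ 0.6) per (ratio, class) cell is ~12–15% and essentially
irreducible — d behaves like 0.82·u·t with u ≈ 0.5 at the median ratio —
so with tens of background features the background degrees (binomial with
that rate) swamp a 5-edge planted hub; moreover the coupled partners are
near-clones of the hub with respect to background features, so any
background node that null-edges the hub receives a correlated burst of
partner edges and out-degrees it.  Degree-ranked hub discovery is
therefore only a clean, reproducible claim in the compact regime; the
statistic-level claims (oracle equivalence, centroid identity, scale
invariance, nesting) are tested at arbitrary sizes, and the generator's
defaults remain study-scale.

## Problem sizes and runtime

The acceptance computations use: 200 random instances (m ≤ 6, n ≤ 30,
z ≤ 4) for oracle equivalence; 100 seeds for hub recovery; 50 seeds for
panel recovery; 100 seeds for longitudinal power; 1000 seeds for the null
rejection rate; 100 seeds for log-rank power at hazard ratio 3, n = 100.
The full suite runs in well under a minute on one CPU.

## Numerical choices and degenerate inputs

* Pooled SD uses the n − z denominator (the standard unbiased pooling).
* s_ij + s_0 = 0 (a globally constant cohort) gives d = 0 with a logged
  warning rather than an error.
* Ratios are computed in the canonical i < j orientation only; the
  raw-ratio statistic is *not* orientation-symmetric, and the canonical
  choice makes edge sets deterministic.
* Preprocessing order: all-zero-group exclusion before imputation, so the
  group minimum used by the 10%-of-minimum rule always exists; residual
  sporadic zeros are replaced by the same rule so ratio denominators are
  strictly positive.  Imputation groups are the class labels.
* Degenerate t-tests (zero variance) return p = 1 when the means agree and
  p = 0 otherwise; paired tests require ≥ 3 complete pairs and drop (and
  log) subjects missing either time point.
* Degree ties are broken by feature-list order and logged.
* Missing-value tokens accepted on input: empty cell, "NA", "NaN".

## Known limitations

* The statistic's null edge rate at the conventional ε = 0.6 is high
  (~12–15% per cell); real-data networks will be dense among
  large-raw-scale ratios, and degree rankings there reflect background
  density as much as signal.  This is a property of the method, faithfully
  reproduced.
* The raw-ratio scale dependence means features with very different
  abundances contribute asymmetrically; log-scale input changes results
  (the reader records which scale was supplied, but no transformation is
  applied).
* The ROC confidence interval is the Hanley–McNeil normal approximation;
  exact binomial variants would differ in small samples.
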
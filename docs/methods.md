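# Methods

This note documents the models, numerical procedures and design choices
behind `spikepairs`, in the spirit of a statistical software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The data model

The atomic object is the pair distribution: for one neuron pair and one
stimulus condition, the first-spike latency pairs `(s0, s1)` on conjunctive
trials (both neurons spiked), restricted to [0, 50) ms after cortical
activation onset. When input latencies are referenced to stimulus onset,
a 5.4 ms activation-onset shift is subtracted at load time. Trials with no
spike for a neuron are simply absent — there are no sentinel values — so
trial indices carry the alignment between neurons and across pairs.

## Synthetic sessions

The generator draws, per condition and trial, a session-wide latent
excitability η ~ N(0, 1) shared by all configured pairs, then per pair a
cluster membership from the configured mixture (any residual probability
mass yields a non-spiking trial), latencies
`mean_i + λ_i·η + drift(t, f) + N(0, σ_i)`, and finally drops each neuron's
spike independently with probability `1 − reliability`. Latencies outside
the 50 ms window are re-drawn up to 10 times and then dropped, which keeps
the window rule without visibly distorting the marginals of well-placed
clusters. Everything is a deterministic function of the config seed.

Adaptation is a saturating exponential in trial index,
`a·(1 − exp(−t/τ))` with `τ = T/ln 10` so that 90% of the drift amplitude
`a` is realised within the first `T` trials (default 20), active only at
stimulation frequencies at or above a configurable threshold; count
depression scales the per-trial spike probability with the same kernel.
This reproduces the qualitative structure of depressive cortical
adaptation — most change in the first ~20 rapid trials — without claiming
a specific biophysical form. A single frequency threshold governs both
latency and count adaptation; real cortex shows count depression only at
somewhat higher frequencies than latency adaptation, which the config can
express by running separate conditions.

What the generator deliberately does *not* emulate: membrane-potential
dynamics, multi-spike responses (only 0/1 first spikes), non-Gaussian
state distributions, regime-switching between clusters over time, and
recording artefacts (sorting errors, drift of spike amplitudes). Passing
tests therefore demonstrate correctness of the *analysis* under its own
statistical assumptions, not robustness to every property of in-vivo data.

Four surrogate constructions support calibration:

* **shuffle** — one margin permuted by a random derangement (no pairing
  survives), preserving both latency multisets exactly;
* **Gaussian** — independent normals matching each margin's mean/sd, same
  sample count;
* **45° replacement** — all samples within a `6·σ̄` circle of a Stage 2
  cluster mean (σ̄ = mean of the two cluster sds) replaced by an equal
  number of draws from a bivariate Gaussian with equal axis sds (σ̄) and
  positive correlation, whose PC1 is therefore exactly 45°;
* **distractor** — a 45° Gaussian at the original cluster mean plus an
  uncorrelated cloud offset along a 15° ray with x-offset `10·σx`.

The replacement Gaussian's correlation magnitude is not dictated by the
construction; we use the source cluster's |r| clipped to [0.2, 0.95], so
the surrogate cluster is about as detectable as the original.

## Cluster extraction

Stage 1 sweeps DBSCAN (min_samples = 5, Euclidean) over
ε ∈ {0.40, 0.45, …, 5.00}. A clustering identical *as a set partition* to
the previous ε's is discarded, as are clusters with fewer than 30 members.
Per partition, each cluster gets an axis-aligned "intersection ellipse"
with semi-axes `3·max(0.5, σ_i)`; any candidate whose intersection ellipse
touches another cluster's is dropped (non-isolated). Ellipse–ellipse
intersection is tested conservatively by sampling 720 boundary points of
each ellipse for containment in the other plus mutual centre containment.
Survivors are expanded to a flat 4σ bounding ellipse whose contents —
*all* distribution points inside it — form the Stage 1 cluster; this
expansion is what keeps the subsequent correlation test unbiased by the
density-based selection.

The sweep's density labelling runs on a precomputed distance matrix:
clusters are connected components of the core-point adjacency graph
(core = ≥ min_samples neighbours within ε, self included) and border
points join their nearest core point's cluster. The test suite asserts
partition-equivalence with scikit-learn's DBSCAN, the only permitted
difference being border points reachable from more than one cluster
(scikit-learn assigns those by traversal order). min_samples and the
metric are exposed as parameters; 5 and Euclidean are defaults, not
claims about the original analysis.

Stage 2 refines every Stage 1 cluster correlated at p < 0.005 with three
bootstrap rounds. Each round draws 10 000 with-replacement resamples,
averages the resampled means and covariance matrices element-wise, and
builds an angled ellipse (rotation = PC1 angle of the averaged covariance,
semi-axes = 4·√eigenvalue); membership is re-selected from the *full*
distribution inside each intermediate ellipse. Identical Stage 1 member
sets re-found at neighbouring ε refine identically and are computed once.
A similarity filter then removes angled clusters sharing ≥ 15 members with
one produced at a lower ε; if several non-overlapping angled clusters
survive in one distribution, the pipeline keeps the lowest-ε one so each
distribution contributes at most one Stage 2 cluster.

Two Gaussian-mixture comparison variants are provided: a plain
BIC-selected GMM (1–10 components), and a "custom" variant that pushes the
GMM components through the same isolation/expansion/bootstrap chain.

## Correlation angles

Per bootstrap resample the PC1 axis angle is computed in closed form
(`tan 2φ = 2·cov / (var_x − var_y)`) and doubled into [0, 360), which
identifies the two directions of an axis and removes the 0/180
discontinuity. The point estimate is the circular (resultant-vector) mean
of the doubled angles, halved; the 95% CI takes the 2.5%/97.5% order
statistics of the doubled angles and halves them. Order statistics are
taken after recentring the doubled angles on their circular mean — for
clouds away from the axes this is identical to raw order statistics, and
for clouds aligned near 0°/180° it avoids wrap-around artefacts.
θ45 = min(θ, 90 − θ) folds out the arbitrary assignment of neurons to
axes (the lower neuron id is always plotted on x).

Significance against the 0° and 45° boundaries is reported as the
one-sided fraction of bootstrap angles at or beyond the boundary on the
far side of the point estimate. For the 45° boundary the package
*additionally* provides a two-sided p (twice the smaller tail mass across
45°), and the cluster-level determination "significantly different from
45°" uses it: because θ45 folds deviations on either side of 45° into
"less than 45°", the one-sided tail fraction would flag truly-45° clusters
at twice the nominal rate, whereas the two-sided p calibrates at 2.5% when
thresholded at 0.025 — which is exactly what the 45°-surrogate calibration
experiment measures. Negatively correlated clouds carry θ only; θ45 and
the boundary tests are defined on (0°, 90°).

Multivariate normality is assessed with the Henze–Zirkler test (via
pingouin); the pipeline reports raw p-values against the fixed thresholds
(0.005, 0.05, 0.025) with no multiplicity correction, matching the fixed
per-cluster decision rules of the analysis.

## Stationarity criteria and detrending

A cluster is *stationary* when (1) its spike times are correlated
(p < 0.005, r > 0.3), (2) neither neuron's latencies regress on trial
index at p ≤ 0.05, (3) a joint linear prediction of the pair from trial
index explains r² < 0.05, (4) both neurons pass KPSS (p > 0.05), and
(5) both lag-1 autocorrelations are non-significant (p > 0.05; this
requirement is waived for differenced series, where the differencing
itself injects a ≈ −0.5 lag-1 autocorrelation, but not for
ARIMA-processed ones). Two further gates admit a cluster to factor
analysis: Bartlett's sphericity test must *reject* (p < 0.05 — the
correlation matrix differs from identity) and the correlation matrix must
have exactly one eigenvalue above 1, which for two neurons reduces to
r > 0. The criteria battery reports raw statistics so either grouping
(stationarity vs factor-analysis gates) can be reconstructed. Note that a
literal reading of the criteria as "Bartlett p > 0.05" would contradict
both the test's role as a factor-analysis pre-test and criterion (1); the
implementation follows the substance.

KPSS is run as the level-stationarity variant with automatic lag
selection (the `regression` argument is exposed): the quantity being
policed is drift of the latency level, and the trend variant would accept
exactly the linear adaptation drifts the battery must catch. Lag-k
autocorrelation significance uses the large-sample ±1.96/√n band.

A neuron's series is differenced when its own trial regression, KPSS or
lag-1 autocorrelation trips (p ≤ 0.05). First differences over
consecutive cluster samples are divided by √2, since differencing
inflates the sd of an i.i.d. series by ≈ √2; when only one neuron is
differenced the partner drops its first sample, so a latency on trial t
stays matched with the difference between trials t and t−1.

The automated Box–Jenkins order selection inspects the lag-1
autocorrelation of the (unrescaled) differenced series: if negative
(r < −0.1) and significant, the series is over-differenced and the
autocorrelation p-values at lags 1–5 are scanned for a sudden cut-off (an
increase from below 0.05 by more than 0.15 between consecutive lags); the
last significant lag is the MA order. A positive significant lag-1
autocorrelation triggers the analogous scan on partial autocorrelations
for the AR order. If the scan finds no cut-off, the last significant lag
within 1–5 is used; series shorter than 8 get orders (0, 0) with a
warning. The ARMA model (statsmodels, constant trend) is fitted to the
unrescaled differences; its residuals are recentred by the
pre-differencing series mean so downstream RDR quantities stay in ms
latency units (the recentring constant is irrelevant to angles and
spreads, which are translation-invariant). Non-convergent fits fall back
to orders (0, 0) with a warning.

## Single-factor state model

For two observed variables the factor decomposition
`Σ = λλᵀ + diag(ψ)` has four parameters against three observable moments
and is identified only up to a one-parameter ridge. The package uses the
canonical maximum-likelihood solution on the correlation scale —
standardized loadings √r for both neurons — giving
`λ_i = sd_i·√r`, `σ_i = sd_i·√(1 − r)`. This choice is *exact* (the
population truth) whenever the residual sds are proportional to the
gains, and in general it recovers the loading *direction* well while the
split between λ and σ along the ridge is not determined by the data; the
recovery experiments therefore use proportional-noise conditions, and σ
estimates on non-proportional configurations inherit the ridge ambiguity.
Iterative EM (e.g. scikit-learn's FactorAnalysis) converges to an
arbitrary ridge point and is used only as a covariance cross-check in the
tests. Heywood cases (r ≤ 0 or r ≥ 1) are rejected with a reason. Factor
scores use the regression method, `η_t = √r·(z0 + z1)/(1 + r)` on
standardized data.

Derived quantities: `σ_diff = √(σ0² + σ1²)` (RDR 3); the within-cluster
difference spread sd(s1 − s0) (RDR 2, computed on detrended values when
the cluster was made stationary); the whole-distribution spread (RDR 1).
With the closed-form fit, RDR3 ≤ RDR2 holds identically in-sample for any
positively correlated cluster (by AM–GM on the margin sds), with equality
exactly when the two margins have equal sds (equal loadings) — the state
then carries no information about the difference.

State prediction projects zero-centred pairs onto PC1, oriented so the
component loadings are non-negative (higher excitability moves both
latencies the same way); cross-cluster state correlations are computed
over common trials for cluster pairs sharing no neuron, with an inclusion
threshold of 15 conjunctive trials. The 4-neuron PCA decomposes the joint
latency matrix of two disjoint pairs on trials where all four neurons
spiked. State-conditioned variability is the residual sd of a linear
regression of the target on the predictor state (regression residuals
rather than binning by state; the choice is labelled in the API). Pooled
example sets keep exactly one entry per response distribution, preferring
the cluster over the unclustered version.

## Calibration experiments and problem sizes

The `calibration` module regenerates every headline quantity from
scratch; `scripts/acceptance.py` writes them as JSON and the acceptance
tests assert them. Problem sizes were chosen as the smallest that make
the binomial/coverage statistics sharp: 2000 surrogates per kind for the
false-positive calibration (parents of 200 trials at 75% reliability,
four surrogate draws per parent); ~400 extracted clusters for the
45°-control; 500 replicates per generative angle (n = 100 points, 3:1
axis sds) for CI coverage, asserted on the pooled 2000 because the
per-angle binomial noise at 500 replicates is ±2% around 95%; ~200
replicates each for factor recovery (six cells over gain ratios
{1, 2, 4} × noise ratios {0.1, 0.3}, 200-trial clusters), detrending
fidelity (120-trial clusters, 3 ms drift) and the state-correlation
experiment (40-trial conditions, 90% reliability, σ/λ = 0.2). All
randomness derives from the single seed passed on the command line.

## Known limitations

* The two-variable factor model's λ/σ split is unidentified off the
  proportional-noise ridge (see above); reported σ_i should be read
  accordingly.
* Border-point assignment in the density labelling can differ from
  scikit-learn's traversal-order rule for points reachable from two
  clusters; partitions are otherwise identical.
* The Box–Jenkins automation considers lags 1–5 only and selects pure AR
  or pure MA components, as appropriate for the short, lightly structured
  trial series it targets; mixed ARMA structure is not searched.
* No multiple-testing correction is applied anywhere; all thresholds are
  the fixed per-cluster rules stated above.
* Dynamic (regime-switching) clustering and nonlinear state models are
  out of scope.
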
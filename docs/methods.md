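# Methods

## Pipeline overview

`brainpred` evaluates how well binary resting-state functional brain
networks can be predicted from anatomical distance combined with a
local-information similarity index.  The pipeline has five stages:

1. **Network construction.**  Regional time series are residualized
   against an intercept plus any supplied nuisance signals (OLS), all
   pairwise Pearson correlations are computed, and the correlation matrix
   is binarized at fixed edge counts m = round(S·n(n−1)/2) for each
   sparsity S in {5%, 10%, …, 40%}.  Rounding is half-away-from-zero;
   since real and predicted networks always share the same m, any fixed
   rule preserves comparability.  By default the m largest *signed*
   correlations are kept (the dominant convention for 90-region binary
   networks); an absolute-value mode is available.  Ties at the cutoff
   are broken by a seeded uniform draw and logged.
2. **Similarity.**  Seven indices (CN, HDI, HPI, LHN-I, PA, RA, SI) are
   computed from the network being predicted — deliberately circular, as
   the question is how much of the network's own edge placement its local
   topology plus geometry explains, not out-of-sample forecasting.
   Pairs with a 0/0 denominator (isolated nodes) score 0 so downstream
   ranking never sees non-finite values; already-connected pairs are
   scored identically to unconnected ones.
3. **Scoring and edge selection.**  P = s^γ/d by default.  The product
   form P = d·s^γ is retained as `distance_mode="literal"`; the penalty
   form is the default because the biological premise is that connection
   probability *decreases* with distance, and with the literal form the
   γ = 0 model would reward the longest edges.  0^0 := 1, so γ = 0 is
   the pure distance model in both forms.  γ is scanned over [0, 3] in
   steps of 0.1 and selected by maximal prediction power (smallest γ on
   ties); an energy-based selection criterion is available but costs a
   full topology profile per γ.
4. **Topology.**  Eight properties per network: assortativity (Pearson
   correlation of edge-endpoint degrees), mean local clustering,
   characteristic path length over *connected* pairs only (5% networks
   are often fragmented; exclusions are logged), global and local
   efficiency, modularity, transitivity, and a truncated power-law fit
   of the degree distribution.  Modularity Q uses the Newman–Girvan
   formula on the partition returned by deterministic greedy
   agglomeration; Q is optimizer-dependent, which is why the optimizer
   is fixed and the partition reproducible.  Undefined metrics (e.g.
   assortativity of a regular graph) propagate as missing values, never
   as zeros.  Each scalar property is summarized by its trapezoidal AUC
   over the sparsity grid, with missing points dropped pairwise.
5. **Evaluation.**  Relative error re = |(p_d − p_m)/p_d|·100% per
   property (AUC scalars for the seven scalar properties; the mean of
   the α and k_c relative errors for the degree fit, taken at the 15%
   reference sparsity).  Energy E = 1/Σre (re as fractions) per subject,
   then averaged — by Jensen's inequality the mean of per-subject E
   exceeds the reciprocal of the mean summed error, so the two
   aggregation orders are not interchangeable.  A perfect prediction
   (Σre = 0) reports a capped sentinel (1e6) rather than infinity.
   Prediction power = 10·log10(Pre_M/Pre_R) with the analytic chance
   baseline Pre_R = m/(n(n−1)/2) by default; a seeded Monte-Carlo
   baseline over random m-edge graphs is available (zero-overlap draws
   are excluded from the baseline mean, with a logged count).  Zero
   recovery reports a −100 dB floor.  Group statistics: exact Wilcoxon
   signed-rank tests (exact null for n ≤ 25; identical vectors report
   p = 1) with Benjamini–Hochberg FDR at q = 0.05 across the seven
   models per property, one-way ANOVA across models for E and for
   power, and the per-model Pearson correlation between E and power.

## Degree-distribution fit

The empirical complementary cumulative distribution P(K ≥ k) over the
observed degree range is fitted to c·k^(α−1)·exp(−k/k_c) on log scale.
The log model is linear in (log c, α−1, 1/k_c), so a weighted linear
solve provides the primary starting value, refined by bounded nonlinear
least squares with four further seeded random starts (guarding the
k_c → 0 boundary); the best residual wins.  Residuals are weighted by
√(N·ccdf) — the inverse sampling standard deviation of a log empirical
CCDF — because with ~10²–10³ samples the unweighted fit is dominated by
the noisy 1/N tail and fails to recover known parameters.  With this
weighting, 1000-sample draws from the fitted form recover α within ±0.2
and k_c within ±20% in every one of 20 seeds (tested).  Networks with
fewer than 5 distinct positive degrees report the fit as missing.

## Synthetic cohort

The generator emulates the statistical structure the prediction models
exploit, not fMRI physics:

* **Geometry** — centroids uniform in a 140×170×120 mm box (the rough
  bounding volume of a whole-brain parcellation), optionally mirrored in
  pairs across the x-midplane for hemispheric symmetry (cosmetic, off by
  a flag).
* **Planted network** — nodes are k-means-clustered into `n_modules`
  spatial modules; pair weights w = exp(−d/λ)·(boost if same module);
  exactly m edges are drawn without replacement with probability ∝ w via
  exponential-race sampling.  Defaults: n = 90 regions, 6 modules,
  λ = 20 mm, boost = 20, S = 15%.  λ and the boost jointly produce the
  distance penalty, triadic clustering and hub structure that make the
  seven indices distinguishable; with boost ≥ 20 and λ ≈ 20 mm the
  resulting graphs are reliably small-world (σ ≈ 3 at S = 15%).
* **Time series** — T = 238 independent draws (the retained-volume count
  of a typical 8-minute TR = 2 s acquisition) from N(0, σ²I + wA) with
  noise σ = 1 and coupling w = 0.6, symmetrized and ridge-regularized to
  positive definiteness when needed (logged).  This covariance form was
  chosen over autoregressive simulation for analytic transparency.

What the generator does **not** model: hemodynamics, autocorrelated or
band-limited noise, motion and drift, inter-subject anatomical
variability, negative couplings.  Passing tests therefore demonstrate
correctness of the pipeline and the qualitative behaviour of the indices
on spatially embedded modular graphs — not quantitative agreement with
any empirical cohort, whose network ensemble is characterized here only
through generic small-world regimes.

## Small-world scalar

σ = (C/C_rand)/(L/L_rand) with the null being means over degree-matched
rewired graphs (10·m double edge swaps each).  Note σ is inflated on
lattices: a C_90 ring with 4 neighbours has σ ≈ 6 purely because its
clustering ratio (~11×) outweighs its path-length penalty (~3×).  The
test suite therefore checks the two ratios separately where lattice
behaviour matters; σ > 1 is used only as a coarse screen for the
generated ensembles.

## Study sizes and numerical choices

The packaged end-to-end study (`scripts/acceptance.py`, `brainpred
study`) uses 12 synthetic subjects at n = 90, T = 238 over the full
8-point sparsity grid — large enough for stable model orderings and
group statistics while keeping a full run in minutes on one core.
Calibration checks use 100 random predictions (chance level), 20 seeds
(degree-fit recovery, index orderings) and 1000 null replicates
(type-I-error calibration of the signed-rank test and ANOVA).

All stochastic steps are pure functions of (inputs, seed): coordinate
sampling, module k-means, edge race, time-series draws, tie-breaks,
rewiring nulls and Monte-Carlo baselines each consume an explicit seed,
and per-subject seeds derive from a single study seed.  Reruns are
byte-identical.

## Known limitations

* Whether thresholding should use signed or absolute correlations is
  genuinely ambiguous in this literature; both are provided and the
  choice can flip which negative-tail edges survive at high sparsity.
* Greedy modularity is a lower bound on the optimal Q; comparisons are
  only meaningful within a fixed optimizer, which is what the pipeline
  guarantees.
* The energy criterion for γ selection evaluates single-sparsity
  relative errors (not AUCs) for tractability inside the scan.
* Assortativity and degree-distribution errors are intrinsically noisy
  on 90-node graphs; they dominate the energy denominator, as reflected
  in the large relative errors the study reports for them.
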
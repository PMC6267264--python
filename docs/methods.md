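# Methods

## Pipeline model

`netsig` treats a cohort study as a fixed chain of estimators over one
ordered ROI set (the `RoiSet`, default 43 labels; its order is the
canonical row/column order of every matrix).

**Structural branch.** A subject's tractography matrix holds directional
streamline hits `0..N` (`N = 20,000` Monte-Carlo streamlines per seed
region). The two directions are combined by the arithmetic mean (a
maximum rule is available via `combine="max"`; the combination rule is a
modelling choice, and the mean is the symmetric, unbiased default). The
subject matrix is binarized against a Poisson noise model: the rate λ is
the mean of the *nonzero* off-diagonal entries (zero entries dominate
sparse connectomes and would collapse the rate toward 0; an all-entries
estimator is available), and the critical count is the smallest integer
`v*` with `P(X >= v* | Poisson(λ)) < α`, default `α = 0.05`, computed with
scipy's Poisson survival function (stable at any λ; verified against a
term-by-term CDF scan for λ up to 50 and against the survival-function
definition at λ up to 2·10⁴). The group adjacency keeps an edge present in
at least `ceil(f·n)` subjects, default `f = 0.5` with an inclusive
boundary (12 of 24 counts).

**Functional branch.** Subjects with summary head motion above 3 mm
translation or 1° rotation are censored before any averaging; missing
motion scalars pass with a warning rather than being treated as motion.
Per-subject ROI-to-ROI Pearson correlations are Fisher-transformed
(`atanh`, with r clipped to ±(1−10⁻⁶) so perfectly correlated synthetic
series stay finite), averaged across subjects, transformed back, and
negative group correlations are set to zero (the edges are removed, not
the ROIs). A single-subject cohort short-circuits the transform — the mean
of one z-score is that z-score — so the round trip is exact to the last
bit.

**Graph layer.** Clustering is triangles over possible neighbour pairs
(binary) or the Onnela geometric-mean-of-weights variant (weighted;
matches `networkx.clustering(weight=...)`). Characteristic path length is
the mean shortest path over *connected* pairs; disconnected pairs are
excluded with a warning and a count, and global efficiency (mean 1/d,
zero for disconnected pairs) is provided as the robust alternative —
relevant here because a strongly modular binary connectome can be
disconnected by construction. Weighted path lengths use `1/w`. Null
ensembles are degree-preserving double-edge-swap rewirings (10·|E|
successful swaps per null, 20 nulls by default); graphs admitting no swap
(complete graphs) are returned unchanged with a warning, and every null's
degree sequence is asserted equal to the input's. Small-worldness is
`γ = C/C_rand`, `λ = L/L_rand`, `σ = γ/λ` against the ensemble means.

**Modularity.** `detect_modules` restarts the Louvain heuristic
(`networkx.community.louvain_communities`, seeded per restart from one
master seed) `n_iter = 1000` times and keeps the partition with the
largest Q, recomputing Q independently from the returned assignment with
the Newman objective `Q = Σ_c [W_c/v − (S_c/v)²]` (v counts both
directions). Ties keep the first partition found, making the result a
deterministic function of (matrix, seed). The published description of
"1000 iterations" could also mean consensus clustering across runs; the
restart-and-keep-max reading was chosen because it is deterministic and
matches how the underlying toolbox is normally scripted. On every graph
with ≤ 8 nodes in the test battery the result equals the exhaustive-search
optimum over all set partitions.

**Density thresholding and the permutation test.** Weighted group matrices
are binarized by keeping the top `floor(d·n(n−1)/2)` positive edges, ties
broken lexicographically by ROI pair so results are reproducible. The
two-cohort permutation test pools subjects, reassigns them to the original
group sizes `n_perm` times, rebuilds each group's network, and reports the
two-sided `p = (1 + #{|Δ_perm| >= |Δ_obs|})/(n_perm + 1)` with the 2.5/97.5
percentile band of the permutation distribution. Two group builders
mirror the two branches: `fisher` (z-average then density threshold) and
`consistency` (mean of subject binary matrices; `density=None` applies the
native `>= f` consistency cut). The distinction matters: at a *matched*
density only differences in edge ranking are visible, so two cohorts
differing only in overall connection probability produce identical
topology after density thresholding — such differences surface at the
native consistency threshold, and that is where the cohort-difference
power test lives. Metrics undefined at a density (empty or fully
disconnected graphs) are reported missing, never interpolated.

**Signatures.** Per subject, each module's activity is the mean over its
ROIs per contrast; the group signature is the subject mean, z-scored
across all module × contrast cells of a study (per-contrast scoping via
`zscore_scope="contrast"`; the published figures do not pin down the
scope, and the study-wide default makes modules and contrasts directly
comparable within a study). Inference is a two-tailed one-sample t-test on
the subject-level module means — a random-effects reading, since the unit
of analysis is not stated in the source description. Zero-variance cells
get `t = ±∞` and an undefined p, never a fabricated one.

**RSA.** Activation RDMs are `1 − Pearson` between ROI contrast profiles
(≥ 3 contrasts required; constant profiles are an error naming the ROI).
Model RDMs encode a partition as 0 within / 1 between. The second-order
statistic is Spearman's ρ over the strict upper triangles (diagonal
excluded — it is structurally zero and would inflate ρ) with average-rank
ties; this choice is consequential because model RDMs are binary and
massively tied, and it is pinned by an independent rank-then-Pearson
oracle to 10⁻¹². Group inference: one-sample t-test over `atanh(ρ)` with
Bonferroni correction over the model × study grid (default 6); the
reported `mean_rho` is the mean raw correlation, the summary comparable to
published per-study r values. Model-to-model comparisons report both the
parametric t-approximation on 903 pairs (anticonservative — RDM cells
sharing an ROI are dependent) and a Mantel-style ROI-label permutation p
(default 10⁵ permutations; for binary RDMs Spearman reduces to a Pearson
correlation of the fixed rank vector with the permuted 0/1 vector, which
keeps the loop cheap).

## Synthetic cohorts (what they emulate, and what they do not)

The generator plants a known partition (demo design: 43 ROIs, five
modules of 9, 9, 9, 8, 8 — within the 5–6 network range typical for
associative-cortex parcellations of this size) and shares it across all
three data types:

* **Streamline matrices** — each direction of each ROI pair carries an
  edge with probability 0.9 (same module) or 0.05 (different modules); a
  present direction carries exactly `streamline_scale = 20,000` hits, an
  absent one Poisson(λ_noise = 2) hits. This reproduces the bimodal
  "high-probability hit vs noise floor" structure the double threshold
  assumes, and makes the noiseless degenerate case exact. It does not
  model distance-dependent tract probability, partial-volume effects, or
  intermediate hit counts.
* **Time series** — `x_i(t) = √ρ·s_m(i)(t) + √(1−ρ)·ε_i(t)` with
  unit-variance Gaussian latent module signals and noise; within-module
  correlation is exactly ρ (`within_corr = 0.5` by default, 128 time
  points, matching a ~6-minute resting scan), between-module correlation
  0. No autocorrelation, hemodynamics, global signal, or motion artifacts
  are simulated; motion enters only as per-subject summary scalars for the
  censoring rule.
* **Task betas** — ROI activity is its module's 3-vector contrast profile
  plus Normal(0, 0.5) noise, per subject and study. Profiles are mutually
  distinct fixed vectors; three studies share the partition and differ
  only in noise.

Passing recovery tests on these cohorts therefore demonstrates that the
*estimators* are correct under the generative assumptions the published
procedure itself makes — not that real tractography or BOLD data satisfy
those assumptions. In particular the planted effect sizes are strong, so
recovered partitions are exact (ARI 1.0) and synthetic RSA correlations
(ρ ≈ 0.6) are an order of magnitude larger than is realistic for empirical
data, where voxel-level noise, imperfect parcellations, and partial
overlap between modality-specific partitions push per-study correlations
down to the few-percent range. One consequence carries over directly: with
~20 subjects, a random-effects RSA detects even tiny but *consistent*
correlations — a label-shuffled control model typically retains a small
nonzero correlation with the common activity structure and can reach
significance. The meaningful control comparison is therefore that the
true-partition model *outscores* a shuffled model, which it does in 100%
of seeded replicate runs, not that a shuffled model is never significant.

All generators are deterministic functions of (design, seed): per-subject
substreams are spawned from one `SeedSequence` keyed by a CRC of the
stream name, so outputs are stable across processes.

## Numerical and sizing choices

* Simulation sizes in the shipped tests and the acceptance script: 24
  subjects per branch (12 + 12 in two-cohort calibrations, mirroring a
  half-and-half split of the structural cohort), 200 calibration
  replicates at 200 permutations and a single density (0.2), 100 seeded
  RSA replicate runs, 1000 Louvain restarts, 20 rewired nulls. These are
  the study conditions; larger permutation counts (the published 1000) are
  a parameter away.
* Matrices travel as labelled TSV with 17-significant-digit floats and are
  read back with `float_precision="round_trip"`, so write→read is
  bit-exact.
* Densities outside (0, 1], fractions outside (0, 1], malformed
  partitions (non-contiguous module ids, uncovered ROIs), non-square or
  label-mismatched files, and empty cohorts are rejected up front, before
  any computation.

## Known limitations

* The Poisson rate estimator for the subject threshold is a documented
  assumption (the original fitting procedure is described only by
  citation); both estimator variants are exposed.
* `σ` comparisons use 20 rewired nulls, so `C_rand`/`L_rand` carry
  ensemble noise of their own; the identity-ensemble case is tested
  exactly, the rest statistically.
* Parametric model-to-model p-values ignore RDM cell dependence; the
  permutation p is the one to trust, and both are always reported.
* No voxel-level modelling anywhere: ROI time series, betas, and counts
  are the atomic inputs; tractography, GLM estimation, smoothing,
  filtering, and nuisance regression are upstream of this package.
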
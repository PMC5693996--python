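# Methods

This note documents the statistical machinery implemented in `connstat`,
the assumptions behind the synthetic cohort generator, and the numerical
and design choices that were genuinely open.

## Network construction

A subject enters the analysis as a T×N matrix of ROI-averaged signals
(the default parcellation is the 90-region AAL cerebrum; any unique
label set works). The functional network is

1. **Pearson correlation** between every pair of regional time courses.
   A zero-variance regional signal has no defined correlation and is a
   hard error naming the region rather than a silent NaN.
2. **Fisher transform** z = atanh(r), applied after clipping |r| to
   1 − 1e-7. The clip keeps weights finite at numerically perfect
   correlations while preserving the edge ordering; the diagonal is set
   to zero since self-correlation carries no edge.
3. **Rectification**: negative weights are set to zero. The analysis
   space is therefore symmetric, hollow, non-negative matrices — the
   space in which the weighted topology measures below are defined.
   Anti-correlations are discarded, not modelled.

No detrending, filtering or nuisance regression happens here: the
package consumes already-preprocessed time series, and what "clean"
means is the caller's responsibility.

## Network-based statistics

For a contrast between groups A and B (sizes n_A, n_B), each edge gets a
two-sample t statistic for mean(B) − mean(A). Pooled-variance Student t
is the default (the classical choice for this family of tests); Welch is
available by flag. Edges with zero pooled variance get t = 0.

Edges with t strictly above the initial threshold (default 4.20; strict
inequality, so ties at the threshold are excluded) form a graph whose
connected components are the candidate subnetworks. Component size is
the **edge count** (extent), not an intensity sum. The permutation null
reassigns subjects to groups uniformly at random, preserving the group
sizes, and records the maximal suprathreshold component size per
relabelling. The observed labelling counts as one permutation, so with N
permutations the attainable p-values are {1/N, 2/N, …, 1} and

    p(component of size s) = #{null max sizes >= s} / N.

Components with p ≤ α are significant; this controls the family-wise
error rate across the whole network under group exchangeability (the
test suite verifies ≤ 0.075 empirical FWER at nominal 0.05 over 200 null
cohorts).

The default tail is one-sided (t > threshold on the stated contrast),
matching a directional reduction hypothesis; `tail="two_sided"`
thresholds |t|.

For small cohorts `exact=True` enumerates all C(n, n_B) relabellings,
making the permutation p equal to the exhaustive-enumeration p; the
suite checks this equality on 3-vs-3 cohorts against an independent
oracle.

**Hubs.** A component's hubs are regions whose degree within the
component exceeds the degree mean by more than two sample standard
deviations. Two populations for the mean/sd are supported: the
component's own nodes (`hub_detect(component)`), and the full
parcellation with untouched regions counted at degree zero
(`NBSResults.hubs(scope="parcellation")`, the default on results).
Whole-brain hub reports implicitly use the second convention — isolated
regions pull the mean toward zero, so moderately connected component
nodes (degree 3–4 out of 90) are correctly flagged, which
component-restricted statistics would miss. Both are exposed because the
choice genuinely changes the answer.

## Weighted topology measures

Brain-Connectivity-Toolbox conventions throughout; weights are
affinities, and distance computations use edge length 1/w.

- **Strength**: Σ_j w_ij.
- **Clustering** (Onnela): ŵ = w / max(w); C_i = 2/(k_i(k_i−1)) ·
  Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}; zero when degree < 2. Bounded in
  [0, 1] and invariant to uniform weight scaling.
- **Nodal efficiency**: (1/(N−1)) Σ_{j≠i} 1/d_ij with Dijkstra
  distances; unreachable pairs contribute zero. "Regional efficiency" is
  ambiguous between this and the local-subgraph variant; both are
  implemented (`variant="nodal"` default, `"local"` optional).
- **Betweenness**: unnormalized Brandes betweenness; tied shortest paths
  split credit fractionally, with no arbitrary tie-breaking.

The implementations are thin layers over networkx and
scipy.sparse.csgraph; the test suite validates all four against
exhaustive simple-path enumeration oracles on 100 random graphs of up to
10 nodes at 1e-9.

## Clinical associations

Partial Spearman correlation: the feature and the score are
rank-transformed (average ranks on ties), both rank vectors are
residualized on an intercept plus the ranked covariates by least
squares, and rho is the Pearson correlation of the residuals. The
p-value uses t = rho·√((n−2−k)/(1−rho²)) on n−2−k degrees of freedom,
two-sided; at the n ≈ 46 scale this t approximation is accurate, so no
permutation p is offered. With zero covariates the procedure reduces
exactly to ordinary Spearman correlation, which the suite asserts, and
it is cross-checked against an independent implementation (pingouin's
inverse-correlation-matrix route) at 1e-10.

Covariates are age (years), gender (0/1, entered linearly on ranks) and
education (years). Subjects with missing covariates are dropped with a
logged warning; fewer than 10 remaining is an error. Associations run on
the pooled patient sample by default.

FDR uses Benjamini–Hochberg step-up within a family. Families are:
all subnetwork edges for one score (edge associations), and all
(hub, metric) pairs for one score (metric associations); a
`family_mode="per_metric"` alternative corrects within each metric
separately, since published reports are often ambiguous between the two.
Degenerate features (constant after ranking) yield rows marked invalid
rather than poisoning the family.

## Synthetic cohorts

The generator emulates the statistical structure of the motivating
study, not its biophysics.

- **Design**: 23 + 23 patients and 36 controls by default, with age
  drawn uniformly from 45–68 years, education from a clipped
  N(11.6, 4.3²), and gender Bernoulli(0.171) — the demographic profile
  being emulated. Covariates are independent of everything else, so any
  covariate adjustment downstream is exercised but unconfounded.
- **Edge mode**: each unplanted edge gets one latent mean
  N(background_mean, background_sd²) shared by all groups (so unplanted
  edges are exchangeable by construction); each planted edge takes its
  per-group mean. Subject weights are N(mean, edge_sd²) truncated at
  zero. The truncation matches the rectified network space; it biases
  very low means upward by up to ~0.04 z at mean 0.06, sd 0.1, which is
  part of the modelled reality of rectified networks. Gaussian edge
  noise is a modelling choice, not an empirical claim.
- **Defaults**: background_mean 0.4, background_sd 0.1, edge_sd 0.1.
  Within-group edge sds are not published for the emulated study; the
  printed t statistics imply roughly 0.13–0.19, so 0.1 is a slightly
  optimistic but same-order choice and remains a free parameter.
- **Time-series mode**: the per-group target correlation matrix is
  tanh of the z means, projected to the nearest positive-definite
  correlation matrix (Higham-style alternating projections, tolerance
  1e-8, at most 100 sweeps; already-PD targets are passed through, and
  failure to reach positive definiteness is a labelled error). Subjects
  are zero-mean multivariate normal draws (default T = 200 volumes —
  at TR 3 s a 10-minute scan, a typical resting acquisition length);
  sample correlations converge to the projected target as T grows.
- **Scores**: severity scores couple to the summed planted-edge weight
  through a Gaussian copula. The latent severity is ρ_p·z_x +
  √(1−ρ_p²)·ε with ρ_p = 2·sin(π·ρ_s/6), where z_x are normal scores of
  the subnetwork weight; this hits the target population Spearman ρ_s
  exactly before discretization. Integers are produced by
  round-half-away-from-zero and clamping to instrument ranges
  (suicidality 0–33, SSI 0–38); at ~30 levels the ties introduced by
  rounding attenuate |ρ| by well under 0.01. Coupling is applied within
  the patient sample (where associations are computed); depression,
  anxiety and impulsivity scales are uncoupled noise, emulating their
  null associations; controls get low-range noise scores.
  |score_coupling| = 1 is rejected as unsatisfiable with noise.

**What passing tests on these cohorts does and does not show.** The
generator reproduces the target effect sizes, exchangeability under the
null, and the rank-coupling between connectivity and severity. It does
not simulate BOLD autocorrelation, motion or physiological artifacts,
site effects, or realistic between-edge correlation structure; power and
calibration results on synthetic cohorts are therefore statements about
the statistics under the stated model, not about any real acquisition.

## Reproducibility and problem sizes

All randomness flows from `numpy.random.Generator` objects seeded
explicitly; identical (spec, seed) gives bit-identical cohorts, and the
pipeline expands its single seed into per-stage substreams by stable
hashing of stage names, so adding a stage does not shift earlier
streams. Reports are deterministic up to the provenance timestamp.

Problem sizes used in the validation suite are the package's own
choices: the subnetwork-recovery experiment runs the full 90-region,
46-subject design at 1000 permutations; the FWER study uses 200 null
cohorts at 500 permutations; estimator-recovery uses 500 replicate
46-subject cohorts on a 12-region parcellation (the estimand does not
depend on parcellation size); topology oracles use graphs of at most 10
nodes, where exhaustive path enumeration is feasible.

## Known limitations

- Negative-weight network analysis is out of scope; rectification is
  built in.
- The NBS implementation covers two-group contrasts only (no F-tests,
  ANCOVA designs, or threshold-free cluster enhancement); component
  statistics are extent-based, not intensity-based.
- The association layer offers the t-approximation p only, which
  degrades below n ≈ 15.
- The permutation engine holds the subjects×edges matrix densely in
  memory — fine at N = 90 (4005 edges), not designed for voxel-level
  meshes.
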
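# Methods

This note documents the models, conventions, and numerical choices behind
`microassembly`, and what the synthetic-data experiments do and do not
demonstrate about real amplicon data.

## Data model and rarefaction

The central object is an integer OTU count matrix with samples as rows.
Readers accept the classic OTU-table TSV layout (rows = OTUs, first column
the OTU id) and BIOM-JSON, and record the detected orientation.  Counts are
validated on construction: non-negative, integral, unique ids.

Rarefaction subsamples each sample to a fixed depth **without replacement**
(multivariate hypergeometric), matching the single-rarefaction behaviour of
standard amplicon pipelines; samples below the target depth are dropped and
their ids reported.  The default depth is 10,000 reads per sample.  OTUs
that end up with zero total count are retained in the matrix but flagged;
downstream prevalence filters remove them.  All randomness is driven by an
explicit seed.

Relative abundances for trait thresholds are computed on the rarefied
table.

## Trait partitions

*Abundant* OTUs exceed 1% relative abundance in at least one sample
(strictly; exactly 1% is rare); all other OTUs are *rare*.  The two classes
are exhaustive.

The Levins niche-breadth index of OTU *j* is `B_j = 1 / sum_i q_ij^2`,
where `q_ij` is OTU *j*'s abundance in sample *i* divided by its total
abundance over all samples.  `B` ranges from 1 (single-sample OTU) to the
number of samples (perfectly even spread).  OTUs in the top 10% of `B` are
*generalists*, the bottom 10% *specialists*, and every OTU tied at the
minimum `B` is a specialist regardless of how large the tie group is.

Percentile conventions, made explicit because they decide reproducible
counts: the top-10% cut is the value of the `ceil(0.10 * n)`-th largest
`B` (nearest rank), inclusive at ties, so `n` distinct values yield exactly
`ceil(0.10 n)` generalists; likewise for the bottom cut.  When ties make
the generalist and specialist rules overlap, the specialist rule wins, so
an OTU attaining the minimum `B` is never a generalist.

## Distance decay

Community similarity is 1 − Bray–Curtis dissimilarity on the rarefied
counts.  Geographic distance is the haversine great-circle distance (Earth
radius 6371.0 km).  Similarity is regressed by OLS on log10 distance;
zero-distance pairs (resampled sites) are offset to half the minimum
nonzero distance before the log.  A linear-distance fit is available as a
config switch.

Because the `n(n−1)/2` pairs are not independent, the OLS p-value is
anticonservative; a Mantel-style permutation p (sample labels of the
similarity matrix permuted, 999 permutations, two-sided on the Pearson r)
is reported alongside and is the value to trust for significance.  A
degenerate input (no variance in similarity or distance) is flagged and
returns slope = r = 0.

## Sloan neutral community model

Under neutral dispersal and drift, a taxon with metacommunity relative
abundance `p` has local relative abundance distributed
`Beta(Nm * p, Nm * (1 − p))`, where `Nm` is the product of local community
size and immigration rate.  Its expected occurrence frequency above a
detection limit `d` is

    F(p) = 1 − BetaCDF(d; Nm p, Nm (1 − p)).

The fit takes each OTU's pooled relative abundance (`p`, the OTU total over
the grand total — equal to the mean per-sample relative abundance on a
rarefied table and invariant to shuffling counts within an OTU) and its
observed occupancy (`F_obs`, fraction of samples with count > 0), then
estimates `Nm` by bounded non-linear least squares over `log10(Nm)` in
[0, 9] with multiple starts (SSE tolerance 1e-10).  `R² = 1 − SSres/SStot`
may be negative (anti-neutral occupancy clouds, e.g. habitat specialists)
and is undefined when occupancy has no variance (every taxon seen in every
sample).  The immigration rate is `m = Nm / depth`.  Per-OTU 95% envelopes
are Wilson score intervals on `F_pred` at `n = n_samples`, and OTUs are
partitioned into above/within/below the envelope.

**Detection limit.**  `d` defaults to `ln(2) / depth`.  Detection by count
sampling at depth `N` is soft — a taxon at proportion `q` is seen with
probability ≈ `1 − exp(−qN)` — and the sharp threshold that matches it
(detection probability 1/2) is `q = ln 2 / N`.  Under beta-multinomial
sampling the common convention `d = 1/N` systematically overestimates `Nm`
by roughly 25%, which `ln 2 / N` removes; `d` remains an explicit argument
for users who want the `1/N` convention.

## Canonical correspondence analysis

With relative frequency matrix `P`, row masses `r` and column masses `c`,
the chi-square standardized residual matrix is
`Q = (P − r c') / sqrt(r c')`; total inertia is `||Q||²`.  Constraints are
weighted-centred and scaled, collinear columns dropped by greedy
rank-revealing pruning, and `Q` is projected onto the constraints in the
`sqrt(r)` metric by least squares.  The SVD of the fitted matrix gives the
constrained eigenvalues; the residual gives the unconstrained ones; the two
always sum to the total inertia.  The constrained proportion is the
constrained share of total inertia.

Per-factor significance is a **marginal** permutation test: the tested
column is permuted across samples while the other constraints are held
fixed, the statistic is the partial constrained inertia of the factor given
the others, and `p = (exceedances + 1)/(n_perm + 1)` (999 permutations,
unrestricted row permutation).  Variation partitioning reports each
constraint group's partial (conditional) proportion with the remainder as
the shared component; components may be slightly negative and are reported
as-is.  Note that with strongly collinear factors (e.g. climate covariates
that track latitude) most explained inertia lands in the shared component
and individual marginal tests can all be non-significant while the total
constrained proportion is substantial — the worked example shows exactly
this.

The ordination method is fixed to CCA; the detrended-correspondence
axis-length screen used to choose between CCA and RDA is out of scope and
recorded as a config constant.

## SparCC co-occurrence networks

Only OTUs exceeding 0.1% relative abundance in at least one sample
(strictly) enter the network.  SparCC estimates basis correlations from
log-ratio variances `t_ij = var(log(x_i/x_j))`: under the sparsity
assumption the basis variances solve `[(D−2) I + 1 1'] w² = rowsums(T)`,
correlations follow as `ρ_ij = (w_i² + w_j² − t_ij)/(2 w_i w_j)` (clipped
to [−1, 1]), and the most strongly correlated pairs are iteratively
excluded from the system (10 rounds, exclusion threshold 0.1).  Fractions
are resampled from a per-sample Dirichlet posterior (counts + 1, 20 draws)
and the reported `r` is the median across draws.  Pseudo p-values permute
each OTU's counts across samples independently and compare `|r_perm|` to
`|r_obs|` (add-one rule, 100 permutations by default; permutation
replicates use 5 Dirichlet draws since the null median is insensitive to
the draw count).

Edges are kept when `|r| > 0.6` and `p < 0.05`; the absolute-value rule
retains negative associations (a `positive_only` flag restores the literal
one-sided reading).  Isolated nodes are dropped from the graph and logged.

Topology: degree; shortest-path betweenness (normalized); harmonic
closeness divided by `n − 1` (well defined on disconnected graphs); local
clustering (degree < 2 contributes 0); diameter of the largest connected
component.  *Hubs* are nodes in the top 30% of both degree and
betweenness; *keystones* combine top-30% degree and closeness with
bottom-30% betweenness.  Cuts are nearest-rank and inclusive at ties with
a small numeric tolerance (tied metrics can differ in the last float bit
depending on summation order); a node satisfying both rules — possible only
when ties collapse the cuts — is labelled hub, keeping the two roles
mutually exclusive.  "Degree centrality" and "mean degree" are treated as
the same node-level quantity.

Pathway annotations (CBB, WL, ASR, DSR, SOX, nitrogen fixation,
dissimilatory nitrite reduction) are consumed from a precomputed OTU →
pathway table and overlaid on the network as node booleans with per-pathway
node fractions; predicting them is out of scope.

## Mapper / SAFE

Samples are projected to a 2-D lens by classical metric MDS on the
Bray–Curtis distance matrix (double-centring + top-k spectral coordinates;
signs fixed so the largest-magnitude loading on each axis is positive).
The lens plane is covered by `resolution × resolution` rectangular bins per
dimension (default 40), each widened symmetrically by `overlap × width / 2`
per side (default overlap 0.75).  Within every cover cell, samples are
grouped by DBSCAN-style density clustering with `eps` set to the 98th
percentile of the **global** pairwise-distance distribution and minimum
cluster size 2; each cluster becomes a node and nodes sharing a sample are
linked.  "Resolution" counts bins per lens dimension and the SAFE
neighborhood is 1 graph hop; neither convention is forced by the method and
both are explicit config.

SAFE scores a per-sample variable per node: the node value is the mean over
member samples, the neighborhood value the sum over nodes within one hop
(including the node), and the null is built by shuffling the
sample-to-value assignment (default 1000 permutations).
`p = (exceedances + 1)/(n_perm + 1)`; the SAFE score is `−log10(p)`
normalized by the minimum attainable p, hence in [0, 1] with 1 exactly at
the minimum p.  A node is *enriched* when its Benjamini–Hochberg-adjusted
p (across nodes, per variable) is below 0.05.  The dominant-variable map
labels each node with its highest-SAFE enriched variable (lexicographic
tie-break, logged) or `none`.

## Synthetic data: what it emulates and what it does not

The generator mirrors the distributional assumptions the analyses test:

* **Neutral assembly** — per-taxon latent proportions
  `Beta(Nm p, Nm (1−p))` renormalized per sample and sampled multinomially
  at fixed depth, so per-sample totals equal the rarefaction depth exactly.
  Shape parameters that underflow fall back to Bernoulli presence.
* **Spatial turnover** — two endpoint metacommunities (log-normal tilts of
  the base composition, sd `tilt_sigma`) mixed exponentially along a model
  coastline.  The planted decay is approximately log-linear while
  `strength × extent ≲ 2`; beyond that the mixing saturates and steeper
  plantings no longer steepen the fitted slope.  Strong tilts
  (`tilt_sigma ≈ 1.5`) also create taxa effectively endemic to one end of
  the gradient whose niche breadth rivals habitat-confined specialists —
  a real confound of occupancy-based niche indices, visible in the worked
  example (specialist recall 0.8 under a strong gradient vs 1.0 without).
* **Specialists** — k taxa confined to a single habitat label with a
  boosted share inside it; counts are re-drawn per sample so totals stay at
  depth, and presence inside the habitat is guaranteed.
* **Correlated taxa** — a Gaussian copula on log abundances with a target
  correlation matrix, then compositional closure and multinomial sampling.
  Closure happens before sampling, so planted correlations survive only
  approximately; recovery tolerances account for this.

Simulated tables have no taxonomy, no sequencing error or primer bias, no
true ecological interactions (the planted correlation is distributional,
not mechanistic), and climate covariates that are smooth functions of
latitude plus noise.  Passing the recovery tests therefore shows the
estimators are correct under their own generative assumptions — not that
real mangrove-sediment communities satisfy those assumptions.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is deterministic given
it (SparCC equality across runs is statistical, since Dirichlet draws
depend on RNG stream order).  The test suite and the acceptance script use
desk-scale sizes chosen so each stage's signal is comfortably detectable:
neutral recovery at 200 samples × 500 taxa × depth 10,000 over 10 seeds;
SparCC recovery/calibration at 200 samples × 50 taxa; distance decay at 60
samples over 10 seeds with 199 label permutations; Mapper/SAFE at 80
samples over 10 seeds with 300 permutations; graph-metric oracles on 100
random graphs of ≤ 15 nodes.

## Known limitations

* The NCM fit estimates `Nm` only; `N` and `m` are not separately
  identifiable, and `m = Nm/depth` inherits the rarefaction depth as the
  community-size proxy.
* SparCC p-values at the default 100 permutations have a resolution floor
  of ~0.01; edge significance near the 0.05 cut is coarse.
* The Mapper graph depends on cover conventions; comparisons across tools
  require matching the bin and overlap definitions.
* VPA components are raw (not adjusted-R²) proportions, as in the
  CCA-based formulation.
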
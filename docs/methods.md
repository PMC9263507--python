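# Methods

## Model and scope

`richconn` analyzes structural brain networks in which the 90 cerebral
regions of the AAL parcellation are nodes and white-matter connections are
edges weighted by fractional anisotropy (FA), a unitless scalar in [0, 1]
that indexes white-matter integrity. The package consumes per-subject
symmetric non-negative connectivity matrices (or streamline summary records
from which it builds them) and produces group-level statistics: which
regions differ between cohorts, which regions are network hubs, which
hub–hub ("rich-club") connections are abnormal, and how network properties
relate to clinical variables. Image acquisition, preprocessing and
voxel-level tractography are out of scope; the streamline interface starts
at summary records (endpoint regions, per-step FA samples, minimum FA,
maximum turning angle).

## Network construction

A streamline is usable when tracking would not have terminated along it:
minimum FA ≥ 0.2 and maximum turning angle < 45° (the angle bound is
exclusive: a 45° turn terminates tracking), with both endpoints assigned to
distinct regions. The FABIRC weight of a region pair is the average FA of
its streamlines. "Average FA" is read as the mean over per-streamline mean
FA, which weights each streamline equally regardless of length; a pooled
variant (mean over all FA samples of all streamlines) is available via
`build_fabirc(..., pooled=True)`. The per-streamline reading is the common
one and is robust to unequal streamline lengths.

Input matrices are symmetrized by averaging with the transpose; asymmetry
above 1e-6 raises a warning rather than an error because tract counting
can produce one-sided entries. Negative or NaN entries are rejected.
Sparsity thresholding is available (`apply_sparsity`, default grid
0.10–0.34 step 0.01 with AUC aggregation) but off by default: the default
analysis runs on the raw weighted matrix. Ties at the sparsity cutoff are
broken toward the lexicographically smaller node pair, which makes
thresholding idempotent and edge sets monotone across thresholds.

## Graph metrics

Edge weights are affinities; path computations use lengths `1/w` (the
standard choice for FA-weighted analyses; `neg_log` is available for
weights in (0, 1)). Shortest paths are Dijkstra via
`scipy.sparse.csgraph`; betweenness is Brandes via networkx, reported as
unnormalized unordered-pair counts with fractional splitting over tied
shortest paths. Disconnected pairs contribute 0 to efficiencies and are
excluded from path-length means (the common toolbox convention); a node
isolated from everything has nodal path length +inf, which the comparison
layer treats as untestable rather than silently numeric.

Degree centrality is binary degree (presence of any connection), with
strength (sum of weights) always reported alongside, since hub ranking in
this design is degree-based. Weighted clustering is the Onnela
geometric-mean form normalized by the network-wide maximum weight; binary
clustering is triangle density. Note a consequence of the per-network
normalization: all of one subject's clustering values share the subject's
max-weight factor, so within a single cohort draw the 90 node-level
clustering tests are positively correlated (their p-values move together).
The marginal type-I rate per node is still the nominal alpha, which is
what the calibration tests measure across seeds.

Small-worldness compares the observed clustering and path length to
degree-preserving Maslov–Sneppen rewired nulls: gamma = Cp/⟨Cp_null⟩,
lambda = Lp/⟨Lp_null⟩, sigma = gamma/lambda, sigma > 1 indicating
small-world organization. Each accepted double-edge swap carries the two
edge weights to the swapped endpoints, so the null ensemble preserves both
the exact degree sequence and the weight multiset. Defaults: 100 null
networks, 10 successful swaps per edge within a 20x attempt budget,
seeded; graphs admitting no valid swap (a triangle) return unchanged with
the realized swap count logged. The swap loop is compiled with numba when
available; a semantically identical Python fallback keeps results
reproducible without it (same pre-drawn randomness, same sequence of
accepted swaps).

## Rich club, hubs, edge classes

phi(k) is the density of edges among nodes with binary degree strictly
greater than k; phi_w(k) is the mean weight of the club's present edges.
Both are reported side by side because "average connection weight" and
"density of connections" are distinct quantities; clubs with fewer than
two members are flagged undefined (NaN), never silently zero.
phi_norm(k) divides by the mean phi over rewired nulls at the same k.

Hubs are identified on the degree profile averaged across all subjects of
the groups being compared (not per subject): either the 13 highest-degree
regions (ties to the smaller AAL index, logged) or regions at least one
population SD above the profile mean, boundary inclusive. Whether the SD
is population or sample changes the threshold by <1% at 90 nodes and does
not alter the worked example; population SD is used. Edges are then
rich-club (both endpoints hubs), feeder (one), or local (none) — a
partition of the edge set. Abnormal-connection counts per node split
incident significant edges by direction; summed over nodes they equal
twice the edge count (handshake identity).

## Group statistics

Comparisons are pooled-variance two-sample t-tests (Welch available) on
values residualized against [intercept, age, sex] with a single OLS fit
pooled across both groups — per-group fits would absorb the group contrast
into the covariate coefficients. Direction follows the sign of t
(group A minus group B): positive = increased/enhanced. Bonferroni uses
the 90-node family within each metric (not 90 x 5 metrics), a deliberate
per-metric-family reading documented here; edge comparisons use the tested
edge count as family. Metrics with no variation across all subjects (for
example binary degree when every subject shares one topology) are flagged
degenerate with t = 0, p = 1 before adjustment, because residualizing a
constant leaves only floating-point noise. Edges with zero weight in every
subject of both groups are skipped with a log entry.

Partial correlations residualize both variables on the covariates and take
Pearson's r of the residuals, with p from a t distribution on n − 2 − q
degrees of freedom; with no covariates this reduces exactly to plain
Pearson. Residual variance at floating-point noise level is flagged
degenerate (NaN). The correlation screen reports raw p < 0.05, matching
the reporting convention of this analysis family.

The ANI pattern rule classifies a six-domain T-score profile as
"ANI_pattern" when at least two domains score at or below the adjusted
mean minus one SD. The boundary is inclusive ("at least one SD below"),
and the daily-living criterion is an upstream input flag, not computed.

## Synthetic cohorts: what they emulate and what they do not

The generator reproduces the statistical structure the analysis assumes:
96 subjects (24 ANI + 24 non-HAND forming the 48-patient group, 48
controls), 90 nodes, 13 planted hub regions — the occipital/subcortical
set (bilateral putamen, precuneus, calcarine, caudate, superior occipital,
plus left thalamus, left middle occipital, right cuneus) that such cohorts
report — wired densely (base edge probability 0.15; +0.30 for hub
incident pairs, +0.60 for hub–hub), FA-like weights (baseline per edge
~N(0.45, 0.05) truncated to [0.25, 0.65]; subject noise SD 0.04), a small
negative age trend on FA (−0.001/year), Table-1-like covariate and
T-score distributions per subgroup, and planted edge effects of
|ΔFA| = 0.04 (~1 subject SD) on the connections the study design
highlights, positive and negative.

One binary topology and one baseline FA field are shared by **all**
subjects, groups included. This is deliberate: it keeps the binary hub
structure stable across subjects (hub identification is then a meaningful
recovery test), and it guarantees that with no planted effects the groups
differ only by noise, so the type-I calibration of the statistics is
testable. The costs are equally deliberate: binary degree does not vary
(its group test is degenerate by construction unless sparsity thresholding
is applied), and there is no between-subject anatomical variability,
registration error, distance-dependent connection probability, or
hemispheric asymmetry. Passing tests on these cohorts certify the
statistical machinery and the planted-feature recovery — not robustness to
the anatomical heterogeneity of real tractography data.

Streamline simulation draws per-streamline FA samples ~N(true, 0.02)
clipped to [0.2, 0.95] over 20–60 steps; contaminant records each violate
exactly one tracking rule (low FA, wide angle, unassigned endpoint,
self-loop) and are indexed in the ground truth, so filter tests can demand
exact removal.

## Numerical and design choices

- All randomness flows from named, spawned substreams of one root seed
  (topology, baseline, covariates, T-scores, subject noise; per-subject
  null-model seeds in the pipeline), so stages are individually
  reproducible and output tables are byte-identical across reruns.
- Result tables are TSV at %.6g; matrices round-trip at %.17g.
- Reports print 1-based AAL indices plus labels; everything internal is
  0-based.
- The AAL→RSN table is a reconstruction from the standard functional
  parcellation literature (the 10-label vocabulary with calcarine, cuneus,
  lingual, occipital and fusiform cortex in VN; putamen, caudate, insula
  and cingulate divisions in SN; posterior cingulate, precuneus, medial
  prefrontal, angular, hippocampal and middle temporal regions in DMN;
  thalamus as its own label). Ambiguous regions carry an `alt_rsn`
  annotation; summaries use the primary label only, for deterministic
  counting. The table is bundled as an editable TSV.
- Problem sizes in the test and acceptance layers (e.g. 100 recovery
  cohorts, 10,000 calibration simulations, 200 power seeds, 20-null
  normalization ensembles) were chosen as the smallest sizes at which the
  binomial/sampling error of the checked rate is well inside the asserted
  margin.

## Known limitations

- Voxel-level tractography is not simulated; the FA/angle rules are
  enforced as record-level predicates, which approximates either a
  whole-streamline or segment-wise termination reading.
- The small-world sigma of a single subject carries Monte Carlo error from
  the finite null ensemble; 100 nulls is adequate for group contrasts but
  not for certifying the sigma of one subject very close to 1.
- Global comparison of gamma/lambda/sigma inherits the null-ensemble Monte
  Carlo noise as measurement error; it is identical across groups in
  distribution and therefore does not bias the contrast.
- No NBS/permutation network statistics, no modularity or community
  detection, no visualization beyond tabular outputs.
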
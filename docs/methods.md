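# Methods notes

## Model and assumptions

The package analyses a single subject's tau-PET SUVR image as a weighted
undirected graph. Inputs are assumed to be already spatially normalized to
a common template grid (nominally 2-mm isotropic); no registration or
resampling is performed, and geometry mismatches between image, atlas and
masks are hard errors rather than silently resampled, because the node
model is defined in voxel units.

Nodes are 3×3×3 voxel cubes at atlas-region centers. "Center" is defined
as the voxel nearest the region's center of mass in voxel coordinates,
with a deterministic lexicographic tie-break. A candidate node is dropped
when any cube voxel leaves the image or the binarized gray-matter mask
(reason `gm_coverage`), or when its cube shares a voxel with any other
region's cube (reason `overlap`; both members of an overlapping pair are
dropped, which keeps selection symmetric and independent of region
enumeration order). Gray-matter binarization uses an inclusive `>= 0.3`
rule; the threshold is configurable. When a study's definitive node list
is known, an explicit include-list overrides rule-based selection. On a
non-2-mm grid the cube is still 3×3×3 voxels; a warning reports the
resulting physical cube size.

Edge weights are absolute differences of node-mean SUVRs, so the graph is
complete except for exact ties. Network distance is the inverse weight;
shortest paths are computed with Dijkstra (scipy's csgraph) on the dense
direct-distance matrix. Global efficiency averages inverse shortest-path
lengths over ordered pairs; pairs with no finite path contribute zero,
the standard weighted-efficiency convention of the common connectivity
toolboxes. No normalization or rescaling of efficiency is applied; all
measures carry SUVR-difference units, are invariant to adding a constant
to the profile, and scale linearly under positive scaling of the profile.

## Staging

The fixed stager uses limbic strength 14.463 (stages 1–2 vs 3–4), limbic
strength 9.867 (1 vs 2) and global efficiency 0.901 (3 vs 4), with values
equal to a threshold taking the lower branch.

The tree learner is a deliberately simplified conditional-inference
procedure: at each node every feature's association with the response is
scored by a rank (Spearman-type) linear statistic; its two-sided p-value
comes from a seeded permutation test (default 9,999 permutations, the
+1-corrected estimator, which is valid and slightly conservative);
p-values are Bonferroni-corrected over features; splitting stops when the
minimum corrected p exceeds alpha (default 0.05) or a branch would fall
below `min_node` rows (default 20). The split point maximizes the
standardized two-sample rank statistic over admissible cuts, tie-broken
toward the smaller value. Leaves are numbered into stages by the
ascending mean of the first feature, matching the convention that stages
order tau severity. This learner shares the statistical skeleton of
unbiased recursive partitioning but is not bit-identical to the R
partykit implementation (different statistic details, permutation rather
than asymptotic p-values). The response variable used to derive a staging
tree is always an explicit argument; no default response is claimed to
reproduce any particular published tree.

## Statistics

- ANCOVA effect size: type-II sums of squares for the categorical group
  term (configurable only by pre-adjusting the design; type II is the
  default because group/covariate order should not matter), partial
  eta squared, f = sqrt(eta²/(1−eta²)). The 95% CI inverts the
  noncentral-F CDF on the noncentrality parameter and converts with
  eta² = λ/(λ + df1 + df2 + 1). Sex enters as a binary covariate.
- Spearman correlations use average ranks and the asymptotic t p-value.
- The dependent-correlation z test (two overlapping correlations sharing
  one variable) uses Fisher transforms with the back-transformed mean
  correlation in the covariance term.
- Chi-square tests of independence are Pearson, without continuity
  correction.
- AUC uses the Mann–Whitney identity; its CI is DeLong's method
  (hand-implemented from placement values); the operating point maximizes
  Youden's J.
- Missing values are handled by analysis-wise complete-case deletion; no
  multiple-testing correction is applied by default since results are
  reported as raw p-values.

## Synthetic data

The generator stands in for a real cohort; it emulates the *inputs* of
the pipeline, not PET physics. A phantom atlas packs disjoint cuboid
regions (default 5³ voxels, enough to host a node cube with margin) onto
a lattice, with a gray-matter prior of 1 inside regions. Each region
belongs to a tier — limbic, temporal, isocortical, off-target — with four
limbic regions by construction, mirroring the four-node limbic-strength
definition.

Subject profiles follow an additive hinge model: region mean =
baseline + amplitude_tier · max(0, severity − onset_tier) + noise, with
severity ~ U(0,1). Defaults: baseline 1.1 ± 0.05 SUVR (typical
non-specific cortical retention), onsets 0.0 (limbic) < 0.30 (temporal)
< 0.55 (isocortical) encoding the canonical medial-temporal-first spread;
the limbic onset of exactly zero makes every measure strictly monotone in
severity, which is what makes noise-free rank-recovery an exact property.
Amplitudes 0.9 / 0.55 / 0.35 SUVR were chosen once so that a 64-region
cohort's limbic strengths span roughly 0–40 and straddle the fixed
staging thresholds; regional measurement noise defaults to 0.02 SUVR and
voxel-level rendering noise is a separate parameter (0.05 SUVR in the
noisy recovery checks). Rendered images put region voxels at the regional
mean plus voxel noise and background at 0.9.

What passing tests on phantoms do *not* show: robustness to registration
error, partial-volume effects, off-target binding, scanner differences,
or atlas misfit — none of which the generator models.

## Problem sizes and numerical choices

Validation uses 64-region phantoms (the scale of a cerebral parcellation
after exclusions), cohorts of 50 subjects for end-to-end severity
recovery and 200 subjects for tree calibration, 200 replicates for the
tree type-I simulation, 500 for effect-size CI coverage, and 1000 for the
dependent-correlation null. Oracle equivalence for shortest paths is
checked on 200 random profiles of up to 7 nodes against exhaustive
simple-path enumeration and a literal Floyd–Warshall, to 1e-9.

The tree type-I simulation draws its features from a simulated cohort's
own limbic strength and global efficiency — strongly correlated measures,
as in real use — rather than from independent synthetic noise; with
correlated features the Bonferroni-corrected test is conservative, which
is the regime the staging analysis actually operates in.

Degenerate inputs: identical node means give zero-weight edges and
infinite direct distances (bridged by any distinct third node); a fully
uniform profile yields zero strength and zero efficiency; a constant
response yields a single-leaf tree; constant features are skipped with a
log entry.

## Known limitations

- The conditional-inference learner is a simplification; threshold
  estimates agree with partykit-style trees to within sampling error, not
  bit-for-bit.
- The exact CI convention for Cohen's f varies between packages; the
  noncentral-F inversion used here has close-to-nominal but not exact
  finite-sample coverage (≈ 94–95% in the package's own simulations).
- Atlas label ids for entorhinal/composite/reference/limbic regions are
  configuration, not constants: published analyses mix parcellations
  (e.g. an entorhinal label from one atlas, a cerebellar-crus reference
  from another), so no id defaults are hard-coded.
- Phantom realism is limited as described above; quantitative claims
  about real scans require real data.
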
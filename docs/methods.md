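# Methods

## Individualized differential SCN

A structural covariance network is only defined across a group, so a
single subject's network deviation is obtained by perturbation: the
normative network `nSCN` is the region × region partial correlation of
regional GMV over the healthy controls of one acquisition site, controlling
for age, gender (0/1 indicator) and total intracranial volume; adding one
patient to those controls and recomputing gives `pSCN`; the difference
`ΔSCN = pSCN − nSCN` is the network change attributable to the patient.
The change is standardized elementwise as

    Z = ΔSCN / ((1 − nSCN²)/(n − 1)),

with `n` the number of controls in the norm (not n+1 after insertion). Two
points deserve emphasis:

- The denominator is the variance-like quantity `(1 − r²)/(n − 1)` itself,
  *not* its square root. The scale of Z therefore grows roughly linearly
  with the norm size and |Z| values in the hundreds are normal. Z is a
  relative deviation index: it is compared across edges, across patients,
  and against permutation nulls, never against Gaussian quantiles.
- Entries of `nSCN` at ±1 make the denominator vanish; we refuse to
  standardize when |nSCN| > 1 − 1e-9. The threshold is a numerical guard,
  not a statistical floor; in practice only duplicated regions trigger it.

Norms are built per site because scanner differences shift both GMV level
and covariance; a patient is only ever inserted into the norm of their own
site. The patient contributes a row to both the data matrix and the
covariate design of the perturbed regression, and covariates are centered
before regression (this affects only the intercept).

Partial correlation is computed by the residual-regression route: regress
every region on [1, centered covariates] by least squares and correlate the
residuals. The pairwise precision-matrix formulation (invert the covariance
of [xᵢ, xⱼ, covariates]) is mathematically identical and is used as an
independent oracle in the tests; the two agree to 1e-10 on random
instances.

## Lesion-side orientation

Homotopic (mirror-symmetric) region pairs are declared in the atlas file
and must form a perfect involution with partners in opposite hemispheres.
Right-lesion patients' ΔSCN and Z matrices are mirrored (rows and columns
permuted by the pairing) so that the left-hemisphere slot uniformly means
*ipsilesional*. Mirroring is an exact involution and an isometry; applying
orientation twice is an error rather than a silent no-op, because a
double-mirrored matrix is indistinguishable from a native one downstream.

The shipped 218-region atlas is synthetic: interleaved left/right pairs
with cyclically assigned eight-network labels (AN, CN, DMN, DAN, LN, SMN,
VAN, VN). It exercises the pipeline at realistic scale but encodes no real
anatomy; any even-sized atlas file with a valid pairing is accepted.

## Network-based statistics

Edge-level inference is a one-sample t of the patients' Z values against
zero (two-sided). Edges with p strictly below `edge_alpha` (default 0.001)
enter a graph; connected components are the inference unit. The null
distribution of the maximal component size is generated by multiplying each
patient's whole matrix by an independent ±1 — valid because under the null
each patient's deviation matrix is symmetric about zero — and the
family-wise p of a component of size s is `(1 + #{perm max ≥ s})/(n_perm + 1)`
(plus-one rule, so p is never 0 and never below `1/(n_perm+1)`). Sign-flip
nulls reuse the fact that squares are flip-invariant, so each permutation
costs one matrix–vector product per edge set rather than a full re-test.
When `2^m` is small an exhaustive mode enumerates all sign patterns and the
Monte-Carlo p becomes exact.

Components are formed from all suprathreshold edges jointly; each
significant edge is then labeled positive or negative by the sign of its
mean Z. A `sign_separated` flag forms per-sign components instead (its null
still uses the joint maximum, which is slightly conservative). A
`two_sample` design (patients vs a control stack, group-label permutation)
is provided for pseudo-patient analyses; the one-sample design is the
default because the question is deviation from the norm itself.

## Downstream analyses

- **Hemisphere/subnet decomposition.** Oriented edges are classed
  ipsilesional (both regions in the left slot), contralesional, or
  interhemispheric, and cross-tabulated by subnet pair and sign; a node
  table counts significant incident edges.
- **Regional GMV.** Two-sample pooled-variance t per region, patients
  (orientation-mirrored rows) vs controls. The FWE threshold is
  `alpha / Meff` with Meff the Li–Ji eigenvalue estimator
  `Σ [1{λ≥1} + frac(λ)]` on the pooled region-correlation matrix.
  Eigenvalues are rounded to 9 decimals before the floor — the estimator is
  discontinuous at integers and an eigenvalue of 2 minus one ulp must not
  contribute a fractional part of ~1 — and the result is clamped to its
  analytic range [1, R].
- **GMV–network association.** Default mode: per region incident to at
  least one significant edge, Spearman correlation across patients between
  the covariate-adjusted GMV z-score (patient residual under the own-site
  control regression, scaled by the control residual SD, then
  lesion-oriented) and the nodal mean Z over that region's significant
  edges; BH-FDR across regions. A spatial mode correlates the group GMV
  t-map with the nodal mean-|Z| map across regions in a single test. The
  nodal summary is a mean rather than a sum so nodes of different degree
  are comparable; a sum reduction is available.
- **Clinical associations.** Pearson partial correlation of a network
  summary with each clinical score, controlling age and gender, p from the
  t transform with df = m − 4; a rank-transform flag gives the Spearman
  flavor. BH-FDR is applied within each score's family (narrowest
  defensible family), and an uncorrected p < 0.01 fallback column is also
  reported.
- **Demographics.** Continuous variables: KS normality check on
  standardized values, then pooled-variance t (normal) or Mann–Whitney U
  reported as a tie-corrected normal-approximation Z without continuity
  correction. Gender: Pearson chi-square without continuity correction —
  this reproduces printed 2×2 statistics from printed counts. A
  summary-statistics t (`t_from_summary`) covers the case where only
  means/SDs/ns are available.

## Synthetic cohort generator

The generator emulates the study design end-to-end: four sites (defaults
122 controls and 112 patients in total across sites, 218 regions), ages
uniform on 40–75 years, TIV ~ N(1450, 120) mL, male fraction 0.65, regional
GMV around 5 mL with marginal SD 0.6 mL, additive age (−0.01 mL/yr), TIV
(+0.002 mL/mL) and gender (+0.15 mL) effects, per-site affine scanner bias,
and iid measurement noise (0.05 mL) added before the site transform so that
within-site correlations are exactly invariant to site bias. These defaults
are documented choices at a realistic scale, not estimates of any dataset.

The generating correlation has within-subnet blocks (`rho_within`, 0.35),
a between-subnet floor (`rho_between`, 0.10) and extra homotopic coupling
(`rho_homotopic`, +0.25). Patient-specific signal enters two ways:

- **Edge perturbations**: chosen edges of the patient-generating
  correlation are shifted by `edge_delta` before a positive-definite
  projection (eigenvalue clipping at 1e-6, renormalized to unit diagonal).
  Because the projection spreads and shrinks infeasible configurations, a
  requested perturbation survives intact only when the perturbed matrix is
  already PD — a clique of moderately raised correlations is; a star of
  six strong edges is not. Validation scenarios therefore inject a clique.
- **Regional atrophy**: a standardized decrease `atrophy_d` on chosen
  regions. Perturbed edges and atrophy regions are specified in
  ipsilesional (left-slot) ids; for the ~50% of patients with right-sided
  lesions, both are mapped through the homotopic pairing, so that
  downstream lesion orientation re-aligns the signal — exactly the symmetry
  the mirroring step exists to handle.

Clinical scores are baseline + coupling × (summed true nodal deviation) +
Gaussian noise, with bounded scores clamped. Every cohort is fully
determined by its seed, and a ground-truth sidecar (perturbed edges,
atrophy regions) is written next to each fixture.

What the generator does *not* emulate: lesion geometry, spatial
autocorrelation within subnets beyond the block structure, non-Gaussian GMV
marginals, site-by-covariate interactions, and missing-data patterns in
clinical scores. Passing recovery tests therefore demonstrate correctness
of the machinery under a faithful covariance model, not performance on real
MRI-derived data.

## Problem sizes and numerical choices

Simulation-based checks run at R = 20 regions with single-site cohorts
(60–120 controls, 30–100 patients) and 200 permutations — large enough for
the asymptotics that the inference relies on, small enough for the whole
suite to run in seconds. The error-calibration check uses 100 null
replicates; power and recovery checks use 25 replicates each. The
acceptance script mirrors these sizes (50 null replicates) and adds one
multi-site end-to-end pass with 500 permutations.

Determinism: all randomness flows through `numpy.random.default_rng`
seeds; identical config + seed yields byte-identical cohorts and output
bundles (file readers use round-trip float parsing so write→read is
bit-exact). Ties in component ordering are broken by descending edge count
then smallest node id. Degenerate inputs (constant residuals, zero-variance
edges with nonzero mean, rank-deficient covariate designs, sites with fewer
than seven controls, norms at |r| = 1) raise named errors rather than
propagating NaNs; a zero-variance edge whose values are all exactly zero is
treated as absent (p = 1).

## Known limitations

- The literal Z formula makes absolute Z scales incomparable between norms
  of different sizes; cross-site comparisons should use ranks or the NBS
  machinery, not raw Z.
- The one-sample sign-flip null assumes each patient's deviation matrix is
  symmetric about zero under the null; heavy asymmetry in the ΔSCN
  distribution at small norm sizes would make the test anticonservative.
  The empirical FWE check bounds this at the sizes used.
- The Li–Ji Meff is one of several eigenvalue-based estimators; others
  (e.g. Galwey) differ by a few percent on realistic correlation
  structures.
- `classify_edges` requires lesion-oriented input and cannot detect a
  matrix that was mirrored twice; the orientation flag on results is the
  guard.
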
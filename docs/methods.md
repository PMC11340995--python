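# Methods

## The harmonization model

Each connection of a fiber-count structural connectome is modeled as a
linear function of two acquisition parameters: spatial resolution
`X_r` (mm, cube root of voxel volume) and maximal b-value `X_b`
(s/mm²), plus their interaction:

    y = b0 + b1*X_r + b2*X_b + b3*X_r*X_b + e,    e ~ N(0, s²)

Coefficients are estimated per edge by ordinary least squares over all
training observations (one row per scan). Assumptions worth stating
explicitly:

* **edges are independent** — each connection gets its own regression;
  no spatial or topological pooling;
* **no subject term** — subject-specific offsets are absorbed into the
  residuals (traveling designs) or into the intercept's sampling
  variability (single-setting designs). This is what lets a fitted model
  harmonize subjects it has never seen: the correction

      y(AP2) = y(AP1) + b1*dXr + b2*dXb + b3*d(Xr*Xb)

  involves only slopes, so whatever subject-specific signal sits in the
  intercept passes through untouched;
* **linearity in the covariates** — adequate over the calibrated range
  (res 1.25–2.3 mm, bval 1000–3000 s/mm²); known to fail for far
  extrapolation in b-value, which the toolkit reproduces as a controlled
  failure mode (see the extrapolation scenario below).

After correction, values are rounded to the nearest integer and then
negatives are clamped to zero, in that order — fiber counts are
non-negative integers. Ties at .5 round away from zero ("round off"
semantics); the rule is centralized in `harmonization.round_half_away`.

Covariates enter in raw physical units without centering or scaling.
Because the correction depends only on the function space spanned by
{1, X_r, X_b, X_r·X_b}, any affine reparameterization of the covariates
leaves predictions unchanged (verified to 1e-8 in the tests); raw units
were chosen so stored coefficients have direct physical meaning
(fibers/mm, fibers per s/mm²).

Fitting requires a design of rank 4 over the observed settings —
at least four settings varying in res, bval, and their product (a full
2×2 grid is the canonical case). Rank deficiency is an error naming the
observed settings, not a silent pseudo-inverse. Model files record the
bounding box of training settings; harmonizing to a target outside it
emits an `ExtrapolationWarning` but proceeds.

## Graph metrics

Four weighted nodal metrics, computed literally on raw fiber counts:

* **strength**: row sum of weights;
* **closeness centrality**: (number of nodes reachable from i) divided
  by the summed shortest-path distances to them, with edge lengths
  l = 1/w. The numerator is the *reachable* count, not the global n−1,
  so disconnected components are handled gracefully; isolated nodes
  score 0;
* **clustering coefficient**: sum over ordered neighbor pairs (j, h) of
  (w_ij·w_ih·w_jh)^(1/3), normalized by k(k−1);
* **local efficiency**: the same form with the triangle-closing weight
  replaced by the inverse shortest distance between j and h inside the
  subgraph induced by i's neighbors (i removed).

Conventions: w = 0 means *no edge* (length ∞), never a zero-length edge;
nodes of degree < 2 have clustering and local efficiency 0 (avoids 0/0);
unreachable neighbor pairs contribute 0 to local efficiency (1/∞ = 0);
ordered-pair summation matches the k(k−1) normalizer so a unit-weight
triangle scores exactly 1.

A deliberate choice: common toolkits rescale weights by the graph
maximum before taking cube roots, which bounds clustering by 1. The
formulas here are applied to raw counts by default — values can exceed
1 — because that is the printed definition being implemented;
`normalize=True` opts into max-weight rescaling (and is cross-checked
against networkx in the tests). Uniform weight scaling by c therefore
scales strength, clustering, and closeness all by c.

## Acquisition-effect ANOVA

Per edge (or per node of a metric), a fixed-effects 2×2 factorial ANOVA:
factor A = b-value level, factor B = resolution level, 1 df each plus
1 df interaction; subjects in a cell are independent replicates; the
design must be balanced (where Type I/II/III sums of squares coincide —
unbalanced input is rejected, not reinterpreted). In traveling designs
the repeated-measures structure is ignored by construction; since a
subject's offset is constant across all four cells it cancels from every
effect sum of squares and only inflates the residual, making the test
conservative, never anticonservative.

Multiplicity: Bonferroni with m = number of edges (n(n−1)/2; 37,401 at
274 regions) or m = number of nodes. Significance requires raw
p strictly below 0.05/m. Maps report −log₁₀ of the corrected p; base 10
is a convention choice recorded here — the significance decision is
base-independent. Summary percentages are printed to the nearest integer,
or to two decimals below 1%.

Degenerate units (zero variance, e.g. absent connections) are flagged
and reported F = 0, p = 1, non-significant. A unit with nonzero effect
against exactly zero residual variance is reported F = ∞, p = 0. The
zero test uses a relative floor of 1e-12 of the total sum of squares to
absorb float dust from integer data.

## Evaluation

* **distance**: mean absolute difference over upper-triangle edges
  (mean L1, in fibers); the single metric behind all distance matrices.
* **fingerprinting**: on a subject-aligned distance matrix, a row is a
  hit iff its diagonal entry is the *strict* minimum (ties fail —
  conservative, and ties are possible after integer rounding). Matching
  direction is row-wise by default, column-wise by flag.
  I_diff = mean(off-diagonal) − mean(diagonal) on the same matrix.
* **KS test**: SciPy's two-sided two-sample statistic with the
  asymptotic p-value.
* **PCA embedding**: edges are z-scored by training mean/sd
  (zero-variance training edges excluded via a recorded mask, keeping
  the transform linear); a 2-component PCA is fitted on the training set
  only and both sets are projected. Component signs are fixed by making
  each component's largest-magnitude loading positive, so embeddings
  are reproducible across runs.

## The synthetic generator: stated world and limits

An observation at setting s for subject k on edge e is

    y = m_e + u_ke + b_e·(x(s) − x(ref)) [+ g·((X_b − X_b,ref)/1000)²] + n,

then rounded half-away-from-zero and clamped at zero — the same
observation rule harmonization uses.

* `m_e`: group mean at the reference setting, log-normal (σ_log = 1)
  with median `mean_count_scale` over a Bernoulli(`density`) skeleton;
  heavy-tailed like real fiber counts. Off-skeleton edges are exactly
  zero at every setting.
* `u_ke`: subject fingerprint, N(0, `subject_sd`²) per (subject, edge),
  constant across settings — the signal identification relies on.
* `b_e`: linear acquisition slopes on a fraction
  `effect_edge_fraction` of skeleton edges (the rest null, so
  false-positive control is testable in the same cohort). Effect sizes
  are specified as *count shifts across the span of the settings grid*
  (`effect_sd_res`, `effect_sd_bval`, `effect_sd_interaction`) and
  converted to raw-unit slopes internally; the truth object stores the
  raw slopes for direct comparison with fitted coefficients.
* `g` (`nonlinearity`): quadratic b-value shift in counts at
  |ΔX_b| = 1000 s/mm²; zero by default, nonzero in the extrapolation
  scenario where training stays at bval ≤ 3000 and the held-out target
  sits at 8000.
* `n`: N(0, `noise_sd`²) scan noise, skeleton edges only.

Defaults (60 regions, 30 subjects, density 0.35, median count 50,
subject_sd 5, effect shifts 10/15/5, noise_sd 2 fibers) state a world in
which acquisition shifts exceed the fingerprint and the fingerprint
exceeds scan noise — the regime the harmonization method targets, in
which the within-subject cross-setting distance starts *above* the
between-subject distance and drops below it after correction. No
quantitative calibration against real acquisitions is claimed; the
magnitudes realize the qualitative ordering, nothing more.

What the generator does **not** emulate: tractography biases (gyral
bias, streamline-count vs SNR coupling), distance- or curvature-
dependent error structure, spatially correlated noise, hub topology, or
heteroscedasticity across edges. A green test therefore establishes
that the statistics behave as designed under the model's own
assumptions and under the one controlled violation (quadratic b-value) —
not that real connectomes satisfy those assumptions.

All draws flow from one seed through a fixed order (skeleton, group
means, effect edges, effect sizes, subject effects, then noise per scan
in subject-major order), so identical configs are byte-identical and the
continuous (pre-rounding) mode pairs exactly with the integer mode.
The continuous mode exists solely for exact-recovery diagnostics
(noiseless cohorts reproduce their generative slopes to 1e-8, which
rounding would otherwise blur to ±0.5 count).

## Numerical choices, edge cases

* Shortest paths: Dijkstra on sparse length matrices (non-negative
  lengths); unreachable = ∞.
* OLS: one `lstsq` factorization of the shared design applied to all
  edge columns; rank checked beforehand.
* Model serialization uses `repr(float)` round-trip decimals — load is
  bit-exact.
* Manifest matrix paths resolve relative to the manifest file; sessions
  default to "1".
* Harmonizing a manifest that mixes source settings tags each output
  session with its source (provenance), since one subject then has
  several scans at the same target setting.
* Setting equality is exact numeric equality — settings are experiment
  keys, not measurements; no tolerance matching.

## Known limitations

* Linear-in-AP corrections only; no quadratic b-value term in the
  *model* (only in the generator, as a violation), no regularization or
  shrinkage across edges, no covariance harmonization.
* No biological covariates (age, sex, diagnosis).
* The ANOVA treats traveling subjects as independent replicates
  (conservative, see above); no mixed-effects alternative is provided.
* Cross-parcellation harmonization is out of scope: all cohorts and
  models must share label-identical parcellations.
* An outlier-screening report for subjects whose same-setting rescan
  distance rivals between-subject distances is advisory only; nothing is
  auto-dropped.
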
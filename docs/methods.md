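# Methods

## The analysis model

The pipeline treats cortical thickness as a field T_i(v) over the vertices
v of a triangulated 2-manifold, one row per subject i. All inference is
mass-univariate ordinary least squares: the same design matrix is fitted
independently at every vertex, and the t statistic of one contrast column
forms a statistic field on the mesh.

Four maps are produced:

1. **Thickness group difference** — T ~ 1 + group + age + sex + meanCT,
   t for the group indicator (HC=0, PI=1, so positive t means thicker
   cortex in patients). meanCT is the per-subject mean thickness over all
   mesh vertices. With two groups this t test is identical to the
   two-group ANOVA (F = t²).
2. **Thickness–PSQI correlation** — T ~ 1 + psqi + age + sex + meanCT;
   the partial correlation is reported as r = t/√(t² + df).
3. **Per-group covariance (SCN) maps** — after residualizing thickness on
   [1, age, sex] at every vertex, each vertex is regressed on the mean
   adjusted thickness of the seed region within one group:
   T = β0 + β1·T_seed + ε, df = n_group − 2.
4. **Interaction maps** — T = β0 + β1·T_seed + β2·M + β3·T_seed·M + ε on
   the adjusted data, with moderator M the group indicator or the PSQI
   score; the β3 t field is the map, df = n − 4. Under 0/1 group coding
   β3 equals the PI-minus-HC slope difference exactly (the model is
   saturated in group); the test suite asserts this identity to 1e-9.

**Two-stage residualization.** The covariance models are fitted on
age/sex-adjusted residuals rather than with covariates inside the model,
mirroring the standard SCN pipeline. This has a quantifiable small-sample
cost: the projection of the product term T_seed·M onto the covariates is
not absorbed by the reduced interaction model, which attenuates the
recovered β3 by roughly 3% at n = 35/group (measured by simulation; the
one-stage fit is unbiased). `interaction_map(..., covariates=...)` fits
covariates jointly for users who prefer the unbiased variant; the
two-stage form remains the default because it is what the field's
published pipelines do.

Vertices with zero residual variance (exact fits, e.g. a vertex equal to
the seed regressor) are flagged, reported with signed-infinite t, excluded
from smoothness estimation, and treated as suprathreshold (p = 0) in
thresholding. Seed vertices are never silently masked: a seed trivially
covaries with itself, and transparency beats hiding it.

## RFT correction

Familywise error is controlled through the expected Euler characteristic
of the excursion set of the t field:

P(max T > t) ≈ Σ_d R_d ρ_d(t), d = 0..2,

with the Worsley closed-form EC densities for t fields (ρ0 the Student
survival function; ρ1 ∝ (1 + t²/df)^−(df−1)/2; ρ2 ∝ t·(1 + t²/df)^−(df−1)/2)
and resel counts R = (χ, L_boundary/2·FWHM⁻¹, area·FWHM⁻²). A closed
2-manifold has no boundary, so R_1 = 0 and R_0 = 2 for the spherical
templates used here; open patches get the boundary term.

**Smoothness** is estimated from the residual field: residual vectors are
normalized to unit length per vertex, and for each edge of length d the
roughness λ = ‖u_a − u_b‖²/d² estimates the variance of the directional
derivative of the unit-variance error field, giving a local
FWHM = d·√(4 ln2/‖u_a − u_b‖²). The global FWHM converts the area-weighted
mean roughness (each edge weighted by one third of its incident triangle
area). A single pooled FWHM drives all p-values; the per-vertex local
field is stored for diagnostics only — the pooled estimator is the
simplest defensible choice and the local-resel variant was deliberately
left out of the inference path.

**Cluster inference.** The field is thresholded at the t whose uncorrected
tail p equals the cluster-forming threshold (default p = 0.001 — the
de-facto default of the surface-statistics toolbox family; always recorded
in the output metadata since the choice is consequential). Connected
components under mesh-edge adjacency are extracted and their areas
measured on the *interpolated* excursion set: each triangle contributes
the sub-triangle fraction above threshold under linear interpolation
(marching-triangles rule). Whole-vertex areas systematically overstate the
continuous excursion area that RFT models — switching to interpolated
areas moved the empirical null cluster FWE from 0.072 to 0.062 at nominal
0.05 in 500-run calibration. Cluster p-values use the standard 2-D
Gaussian-field approximation: expected cluster count E[m] = E[EC] at the
threshold, expected suprathreshold resels E[S] = R₂·ρ0, extent law
P(extent ≥ k) = exp(−k·E[m]/E[S]) for k in resels, and
p_FWE = 1 − exp(−E[m]·P(extent ≥ k)). Which published cluster-size variant
the field's toolboxes implement varies; this one is validated by
Monte-Carlo calibration (peak and cluster null rejection rates 0.054 and
0.062 at nominal 0.05, 500 simulations) rather than by claimed equivalence
to any particular toolbox.

Positive and negative tails are always analyzed separately (the field's
"increased"/"decreased" map convention); the tails are disjoint for any
threshold ≤ 0.5.

## Synthetic cohorts and fields

The generator emulates the case-control design the models assume:

- **Demographics.** Two groups of n = 35. PSQI scores are rounded
  truncated normals — patients on [5, 21] with mean 12.57, SD 3.93;
  controls on [0, 4] with mean 2.26, SD 1.36, enforcing the control
  inclusion rule PSQI < 5. The truncated-normal location is solved so the
  post-truncation mean equals the configured mean (without moment
  matching, truncation shifts the control mean by ≈5%). Ages are normals
  truncated to [18, 80] years (patients 39.3 ± 8.6, controls 34.9 ± 10.7);
  sex is Bernoulli (5/35 vs 9/35 male).
- **Thickness.** T_i(v) = μ(v) + a_age(v)·age_i + a_sex(v)·sex_i +
  1[v ∈ seed]·L_i + (b0(v) + Δb(v)·g_i)·L_i + ε_i(v), with latent seed
  factor L_i ~ N(0, 0.3 mm). Baseline μ = 2.5 mm (typical cortical
  thickness) and a_age = −0.005 mm/year (typical age-related thinning).
  The latent-factor construction makes Δb(v) exactly the interaction
  coefficient the downstream model estimates, so parameter recovery is a
  meaningful test.
- **Noise.** White Gaussian noise (SD 0.1 mm before smoothing) smoothed on
  the mesh by iterated neighbor averaging, y ← (1−λ)x + λ·mean(neighbors)
  with λ = 0.5. One iteration is a lazy random-walk step of squared
  displacement λ·E[edge²], so k = FWHM²/(4 ln2·λ·E[edge²]) iterations give
  an approximately Gaussian kernel of the requested FWHM. The calibration
  is closed-form, and the residual-based estimator — derived entirely
  differently — recovers the target within ~2% on the icosphere
  templates, so smoothing and estimation validate each other
  non-circularly. Default noise FWHM is 4× the mean edge length, enough
  spatial correlation for the RFT asymptotics to hold at the template's
  resolution.

What the generator does **not** emulate: cortical folding and non-sphere
topology, spatially varying true smoothness, non-Gaussian thickness
distributions, hemispheric asymmetries, and measurement artifacts of real
MR pipelines. Passing tests therefore certify the statistical machinery
under the model's own assumptions, not robustness to real-data
violations of them.

## Meshes and seeds

Templates are icospheres: recursive 4-fold subdivision of a regular
icosahedron with projection to the sphere, V = 10·4^s + 2. Six levels give
the 40962-vertex / 81920-triangle hemispheric convention of surface-based
morphometry; analyses and simulations run at s = 4 (2562 vertices,
~5.3 mm edges at 70 mm radius), which keeps the full 500-run calibration
within a coffee break while preserving ≈140 resels at the default
smoothness. Seed regions are geodesic patches (edge-weighted shortest-path
distance, not exact polyhedral geodesics — sufficient for synthetic
patches and testable against an independent Dijkstra oracle). Meshes are
validated on load (index ranges, zero-area triangles, ≤2 triangles per
edge); non-manifold input is rejected, never repaired. Vertex indices are
0-based everywhere, including TSV files.

## Numerical and design notes

- Determinism: every stochastic step derives from a single integer seed
  via independent named streams (cohort vs field noise), and pipeline
  reruns are bitwise identical at the file level.
- Zero-variance guards: residual variance below 1e-10 of the data scale
  flags a vertex; constant seeds, constant moderators and constant
  covariates are rejected with named errors rather than propagating NaN.
- `two_sample_t` defaults to pooled variance (classical form; for the
  emulated cohort's summary table only the pooled form lands on the
  published one-tailed PSQI p-value's magnitude — Welch is off by five
  orders). Welch is available by flag. The sex test is Pearson chi-square
  without continuity correction.
- The demographics generator and tests code sex F=0/M=1 and group
  HC=0/PI=1 throughout, so every signed contrast reads "patients minus
  controls".
- Per-group corrected-map vertex counts are reported descriptively; no
  inferential meaning attaches to one group's covariance map being more
  widespread than the other's.

## Known limitations

- Cluster p-values lean on the Gaussian-field extent approximation; at
  df ≈ 66 and FWHM ≈ 4 edges this calibrates within [0.03, 0.07] by
  simulation, but very low smoothness or tiny df would need permutation
  instead (permutation exists here only as a test oracle, deliberately).
- The smoothness estimator assumes stationarity when pooling; strongly
  nonstationary residual fields would bias cluster p-values.
- One mesh per run: hemispheres are analyzed separately or supplied
  pre-concatenated as a single mesh file; the global mean-thickness
  covariate spans whatever mesh is supplied.
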
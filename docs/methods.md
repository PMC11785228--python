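# Methods

## The synthetic nucleus and what the generators emulate

All default simulations place spots inside a circular nucleus of radius
46 px centered at (128, 128) on a 256×256 px patch. The radius follows from
a 10 µm nucleus diameter at the 0.108 µm/px pixel size of the imaging system
the synthetic data emulates; it is configurable everywhere. Coordinates are
0-based pixels, (x, y) = (column, row), with no half-pixel offset.

Each generator draws candidates from its parent law and keeps the first
`n_spots` (default 46, a pseudodiploid human karyotype) accepted points in
draw order — inside the nucleus boundary and outside any exclusion disc.
Defaults:

| generator | law | key defaults |
|---|---|---|
| CSR | uniform on the bounding box, rejected outside the circle | n = 46 |
| PDS | uniform candidates with a hard minimum inter-spot distance | 10 px |
| UTA / UTHA | uniform seeds; 15 seeds each gain 1 / 2 adjacent spots at seed + ε, ε ~ U[−3, 3] per axis | seeds = 46 − 15·(1 or 2) |
| S2DG / T2DG / TH2DG | 1 / 2 / 3-component Gaussian mixture, equal weights | variance 200 px² when not sweeping |
| 2DGNB / T2DGTNB | S2DG / T2DG plus exclusion discs | one r = 15 px disc at the center / two r = 12 px discs at the mode centers |

Mixture means sit relative to the nucleus center: two modes at ±(0, 25) px,
three modes at (0, −25), (0, +25), (−25, 0). The benchmark sweep crosses 20
covariance sizes evenly spaced in [50, 1000] px² with 8 orientations in
[0, π) (the increment of the original sweep is not specified anywhere, so an
even 20×8 grid is used); replicate k uses grid cell k mod 160. The
covariance is Σ = R(θ)·diag(σx², σy²)·R(θ)ᵀ with σx² = σy² = size by default
(`aspect` controls the axis ratio when anisotropy is wanted; orientation
only matters then). Nuclear-body positions and sizes are likewise
unspecified in the source material, so the defaults above were chosen once
to carve a visible hole in the density and are configurable.

UTA/UTHA reading: the perturbation shift is one independent uniform draw per
axis per adjacent spot (the simplest reading; nothing specifies per-axis
independence). Seed counts are chosen so seeds plus adjacents total exactly
46 before the in-boundary cap; adjacents that escape the nucleus are
replaced by uniform draws so every pattern has exactly 46 spots.

Seeding: one root seed per run; the stream for replicate k of pattern i is
derived as `SeedSequence(seed, spawn_key=(i, k))`, so replicate k is
reproducible independently of how many replicates a run requests.

What the generators do **not** emulate: optical blur and spot-merging at the
diffraction limit, segmentation errors, z-projection artifacts, non-circular
real nuclei, and cell-to-cell variability in spot number. Passing tests
therefore demonstrate correctness of the statistical machinery on idealized
patterns, not fidelity to any particular microscope.

## Metrics

* **Ripley K score.** K(r) = (A/N²)·Σ_{i≠j} I(d_ij ≤ r) on 50 evenly spaced
  radii in (0, r_max], r_max = the nucleus equivalent radius (r = 0 carries
  no information — both K and πr² vanish). The score is the percentage of
  radii with K(r) − πr² strictly positive. No edge correction is applied:
  the estimator is used exactly as defined, and an isotropic correction
  would silently change every value.
* **Graph metrics.** The k-NN graph (k = 10) uses the union rule: an edge
  exists if either endpoint lists the other among its k nearest. Weighted
  degrees are k_i = Σ 1/d², with coincident points floored at d = 1e−6 px.
  Assortativity is the Pearson correlation of endpoint degrees with each
  undirected edge contributing both orientations; zero degree variance
  returns 0 by convention. Modularity runs Louvain on the 1/d²-weighted
  graph (igraph's multilevel implementation, RNG pinned per call for
  determinism) and reports weighted Q. The weighting matters: on an
  unweighted graph, removing 30 of 46 spots under k = 10 leaves a
  near-complete graph whose Q collapses to ~0.07 for *every* pattern, which
  would make the metric's spot-number robustness an artifact of graph
  density rather than of the spatial pattern.
* **Moran's I.** Computed per coordinate axis with w_ij = 1/d_ij² and
  averaged over x and y (axes with zero variance are skipped). The
  alternative reading — centered coordinate dot products — is exposed as
  `mode="dot"`; the per-axis average is exactly translation invariant while
  only the dot form is exactly rotation invariant.
* **MNND, dispersion index, density.** MNND is the mean distance to the
  nearest other spot. The dispersion index divides the population variance
  of the C(n, 2) pairwise distances by their mean. Density is n/A.

Undefined cases (n too small, all points coincident, edgeless graph) are
reported as missing values with machine-readable reason codes, never
silently dropped.

## Localization models

* **M1** draws uniformly over the geometry (for mask geometries, uniformly
  over labeled pixels with sub-pixel jitter).
* **M2** centers a Gaussian on the fitted nucleus ellipse with σx = a/3,
  σy = b/3 along the ellipse axes, rejecting draws outside the nucleus.
* **M3** uses the closed form K(r) = C/λ·(1 − exp(−r²/2σ²)); normalized,
  this is the Rayleigh CDF of radial distances, so σ is obtained by least
  squares of 1 − exp(−r²/2σ²) against the pooled empirical radial CDF. The
  constant C/λ cancels under normalization and is treated as a fitting
  amplitude. The radial CDF is the default fit target because it is what
  the derivation actually yields; a pairwise-distance CDF target is exposed
  as an option. Simulation from a fitted M3 draws Rayleigh(σ) radii and
  uniform angles.
* **M4** is the radially shifted Gaussian: radius ~ N(r0, σ²) (rejected if
  negative), angle uniform. The likelihood of the pooled radial distances is
  the plain Gaussian — deliberately without a truncation correction, since
  that is the model as specified; the discrepancy is negligible whenever
  r0/σ is large, which is the doughnut regime the model targets. Priors are
  weakly informative and data-scaled: r0 ~ N(mean(r), std(r)²),
  σ ~ N(std(r), (std(r)/2)²). Sampling is Metropolis–Hastings with symmetric
  Gaussian proposals (defaults: 10,000 iterations, 2,000 burn-in, proposal
  scales 0.5 and 0.25 px, fixed seed); σ ≤ 0 proposals are auto-rejected,
  and acceptance fractions outside [1%, 90%] trigger a rescaling warning.
  Radii are measured from each nucleus's own center and pooled in raw
  pixels; fitting is pooled-then-fitted (one posterior), with per-nucleus
  fitting available by calling the fit per nucleus.
* **M5** fits the same two parameters to pooled pairwise distances. The
  pairwise-distance density is
  P(d) = ∬ P(r1) P(r2) · 2d / (π √(F1 F2 F3 F4)) dr1 dr2 over the support
  where the triangle factors F = (d ± (r1 − r2)), ((r1 + r2) ± d) are all
  positive — the delta-function reduction of the angular integral, Jacobian
  included. Numerically the integrand has inverse-square-root singularities
  at the support edges; the default evaluator integrates with Gauss-Hermite
  nodes in both radii for interior distances (the Gaussian "needle" sampled
  exactly) and switches, within ~15σ of d = 0 and d = 2r0, to the
  substitution r2 = m + w·sinφ that cancels the edge singularity. Heavily
  truncated radial laws (r0 < 4σ) use Gauss-Legendre nodes against the
  truncated density instead of Gauss-Hermite. The grid density is refined
  near d = 2r0 for thin rings, and the result is renormalized to unit
  integral (tolerance 1e−3). The compressed kernel 1/(2 r1 r2) and a
  CDF-differentiation route are exposed as alternatives; the Jacobian form
  is the default because it is the one that matches the Monte-Carlo oracle
  (the compressed form, lacking the d/√(1−u²) factor, does not reproduce
  the simulated distance histogram even after renormalization). The M5
  chain evaluates the log-likelihood through bin probabilities of the
  distance CDF (150 bins), which is robust and fast; priors and chain
  mechanics are as in M4.

In the σ → 0 limit the pairwise-distance density approaches the fixed-ring
law p(d) = (2/π)/√(4r0² − d²) on [0, 2r0]; the implementation reproduces it
to better than 1% and the property suite asserts it.

## Distribution comparison and testing

Wasserstein-1 (∫|F1 − F2|) and the KS statistic come from scipy. The
normalized MSE histograms both samples on shared Freedman-Diaconis bins
computed from the merged sample (at least 20 bins — the metric is
binning-sensitive, so the rule is fixed and shared), and divides the mean
squared difference of density values by the population variance of the
"real" sample's density values; it is intentionally asymmetric. The
Mann-Whitney U test uses midranks; when both groups have ≤ 8 observations
the two-sided p-value comes from exact enumeration of all rank assignments
(correct under ties), otherwise from the normal approximation with tie and
continuity corrections. BH-FDR adjustment is statsmodels' step-up
implementation. Cohen's D uses the pooled (n−1)-denominator standard
deviation; benchmark tables report |D|.

## Benchmark pipelines and problem sizes

The sensitivity benchmark compares every generator against CSR per metric
(BH correction applied across the eight generator-vs-CSR tests within each
metric, matching the reference-group design). The spot-removal experiment
removes k = 1..30 spots uniformly without replacement (an independent draw
per k) and reports PC(k) = |mean_k − mean_0|/|mean_0| × 100 per
(generator, metric); a zero baseline (e.g. the Ripley score of PDS) yields a
missing value with reason "zero baseline" rather than an infinity. The
centered overlay shifts every nucleus to (0, 0), histograms all spots on
64×64 bins spanning ±R, and extracts the central row/column as line
profiles; a two-component 1D Gaussian mixture is least-squares fitted to
each profile and flagged degenerate when the modes collapse within one bin.

Default replicate counts are 1,000 per generator for effect sizes and 500
for the removal experiment — sizes at which every reported quantity is
stable to well under its decision threshold while a full run stays in the
minutes range on one CPU; the original study simulated 100,000 nuclei per
generator, and the pipelines accept any replicate count.

## Known limitations

* The M4/M5 radial likelihood ignores both the r ≥ 0 truncation and the
  nucleus boundary; fits of blob-like data (r0 ≲ σ) are biased toward the
  untruncated model.
* M5 treats the C(n, 2) pairwise distances of a nucleus as independent
  observations (as specified); its posterior spread is therefore
  overconfident, and its acceptance fraction at large pooled samples is low
  unless proposal scales are reduced.
* The UTA/UTHA adjacency shift (±3 px) is absolute while the nucleus radius
  sets the distance scale, so effect sizes involving these generators depend
  on the (configurable) nucleus size.
* Percent-change robustness summaries are undefined for metrics whose
  baseline mean is zero; these are reported as missing, not as zero or
  infinity.
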
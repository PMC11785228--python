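# centrospot

Quantitative analysis of 2D nuclear spot patterns: simulation, clustering
metrics, and generative spatial models.

Centromeres — imaged as fluorescent CENP-C spots in interphase nuclei — are
positioned non-randomly, and perturbations (e.g. condensin II / NCAPH2
knockdown) change how strongly they cluster. High-throughput imaging screens
need a per-cell scalar that detects such changes robustly. `centrospot`
provides the full analysis stack for that problem, working purely from
per-nucleus spot coordinate tables (CSV) and optional nucleus label masks
(16-bit TIFF); everything is testable offline through built-in synthetic
generators.

The package has three layers:

1. **Pattern simulators** — nine generators of 46-spot patterns inside a
   circular nucleus (radius 46 px ≈ 10 µm at 0.108 µm/px): complete spatial
   randomness (CSR), Poisson-disk sampling with a 10 px hard core (PDS),
   uniform patterns with two/three adjacent spots (UTA/UTHA), one-, two- and
   three-component 2D Gaussian mixtures with covariance
   Σ = R(θ)·diag(σx², σy²)·R(θ)ᵀ (S2DG/T2DG/TH2DG), and Gaussian mixtures
   with nuclear-body exclusion discs (2DGNB/T2DGTNB).
2. **Clustering metrics** — per nucleus: the Ripley's K clustering score
   (the fraction of radii r where K(r) = (A/N²)·Σ_{i≠j} I(d_ij ≤ r) exceeds
   the Poisson expectation πr², × 100), assortativity and Louvain modularity
   of the 1/d²-weighted k-NN graph (k = 10), Moran's I with w_ij = 1/d_ij²,
   mean nearest-neighbor distance (MNND), the dispersion index
   D = σ²_d/μ_d of pairwise distances, plus spot number and density.
3. **Localization models** — M1 (uniform), M2 (nucleus-shaped Gaussian with
   σx = a/3, σy = b/3 from the fitted ellipse), M3 (centered radial Gaussian
   fitted via the closed form K(r) = C/λ·(1 − exp(−r²/2σ²))), and the
   radially shifted Gaussian f(r, θ) = (2πσ²)^(−1/2)·exp(−(r−r0)²/2σ²) fitted
   by Metropolis–Hastings either on per-spot radial distances (M4) or on the
   pairwise-distance density P(d) = ∬ P(r1)P(r2)·p(d|r1,r2) dr1 dr2 (M5).
   Model fidelity is scored with Wasserstein distance, normalized MSE, and
   the KS statistic; group comparisons use Mann-Whitney U tests with
   Benjamini-Hochberg FDR correction and Cohen's D effect sizes.

## Worked example

```python
from centrospot import core_io, metrics, models

# three synthetic nuclei each of CSR and of a single tight Gaussian cluster
sets = core_io.make_fixture(["CSR", "S2DG"], 3, seed=42)
table = metrics.compute_metric_table(sets)
print(table[["ripley_k_score", "modularity", "morans_i",
             "mnnd", "dispersion_index"]].round(3))
```

```
            ripley_k_score  modularity  morans_i   mnnd  dispersion_index
nucleus_id
CSR-00000              6.0       0.695     0.879  6.468             9.301
CSR-00001             28.0       0.682     0.793  5.690             9.511
CSR-00002             12.0       0.610     0.964  6.521             8.815
S2DG-00000            94.0       0.627     0.479  3.971             6.313
S2DG-00001            90.0       0.591     0.495  4.936             6.610
S2DG-00002            90.0       0.622     0.444  4.965             6.332
```

The Ripley score separates the tight cluster (≈ 90–94% of radii above the
Poisson expectation) from spatial randomness (6–28%) at a glance, while the
cluster also shows smaller nearest-neighbor distances and a lower dispersion
index.

Fitting the radially shifted Gaussian (M4) to doughnut-shaped data recovers
its parameters:

```python
g = core_io.default_circle()
spots = [models.simulate_radially_shifted_gaussian(
             g, 46, r0=30, sigma=5, rng=core_io.rng_for(42, i))
         for i in range(200)]
fit = models.fit_m4_mcmc(spots, cfg=models.MCMCConfig(seed=0))
print(f"r0 = {fit.r0:.2f}  sigma = {fit.sigma:.2f}")
```

```
r0 = 29.97  sigma = 5.01
```

with a 95% posterior interval for r0 of [29.87, 30.07].

The same operations are available from the shell:

```bash
centrospot simulate --pattern s2dg --replicates 100 --seed 1 --out spots.csv
centrospot metrics --spots spots.csv --circle-radius 46 --out metrics.csv
centrospot fit-model --model m4 --spots spots.csv --circle-radius 46 \
    --iters 10000 --burn-in 2000 --seed 1 --out fit.json
centrospot benchmark --replicates 1000 --seed 1 --out-dir bench/
```

## File formats

Spot tables are CSV with header `nucleus_id,x,y`; coordinates are 0-based
pixels, (x, y) = (column, row), written to 6 decimal places. Label masks are
16-bit unsigned TIFF, background 0, one integer label per nucleus. Flat
key-value YAML files can supply defaults to every CLI subcommand via
`--config`.
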
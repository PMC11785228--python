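"""Shared fixtures: expensive simulation experiments are session-scoped so the
robustness and effect-size cohorts are generated once and reused across test
modules."""

from __future__ import annotations

import numpy as np
import pytest

from centrospot import benchmark as bm
from centrospot import models as md
from centrospot.core_io import default_circle, rng_for

ROBUSTNESS_METRICS = (
    "ripley_k_score",
    "assortativity",
    "modularity",
    "morans_i",
    "mnnd",
    "dispersion_index",
)


@pytest.fixture(scope="session")
def geom():
    return default_circle()


@pytest.fixture(scope="session")
def robustness_result():
    """Spot-removal experiment: nine generators x 500 nuclei x k in 0..30."""
    return bm.run_spot_removal(
        n_replicates=500,
        removal_counts=range(1, 31),
        seed=11,
        metric_columns=ROBUSTNESS_METRICS,
    )


@pytest.fixture(scope="session")
def effect_benchmark():
    """Effect-size benchmark: nine generators x 1,000 nuclei, MNND and
    Dispersion Index vs the CSR reference."""
    return bm.run_benchmark(
        n_replicates=1000, seed=7, metric_columns=("mnnd", "dispersion_index")
    )


@pytest.fixture(scope="session")
def full_benchmark():
    """All eight metric columns at 500 replicates per generator."""
    return bm.run_benchmark(n_replicates=500, seed=5)


@pytest.fixture(scope="session")
def rsg_sets(geom):
    """500 doughnut-pattern nuclei (r0=30, sigma=5), 46 spots each."""
    return [
        md.simulate_radially_shifted_gaussian(
            geom, 46, 30.0, 5.0, rng_for(13, i), nucleus_id=f"rsg-{i:04d}"
        )
        for i in range(500)
    ]


@pytest.fixture(scope="session")
def m4_fit(rsg_sets):
    return md.fit_m4_mcmc(rsg_sets, cfg=md.MCMCConfig(seed=3))


@pytest.fixture(scope="session")
def m5_fit(rsg_sets):
    cfg = md.MCMCConfig(
        n_iterations=2500, burn_in=500, proposal_scales=(0.05, 0.025), seed=4
    )
    return md.fit_m5_mcmc(rsg_sets[:300], cfg=cfg)


@pytest.fixture(scope="session")
def density_mc_errors():
    """Sup-norm error (as a fraction of the peak) of the pairwise-distance
    density against a Monte-Carlo histogram, for ring-like, doughnut and
    blob-like parameter settings."""
    out = {}
    rng = np.random.default_rng(17)
    for r0, sigma in ((30.0, 2.0), (30.0, 5.0), (15.0, 12.0)):
        n = 4_000_000
        r1 = rng.normal(r0, sigma, n)
        r2 = rng.normal(r0, sigma, n)
        ok = (r1 > 0) & (r2 > 0)
        theta = rng.uniform(0.0, 2.0 * np.pi, int(ok.sum()))
        d = np.sqrt(
            r1[ok] ** 2 + r2[ok] ** 2 - 2.0 * r1[ok] * r2[ok] * np.cos(theta)
        )
        edges = np.linspace(0.0, 2.0 * (r0 + 6.0 * sigma), 81)
        hist, _ = np.histogram(d, bins=edges, density=True)
        centers = (edges[:-1] + edges[1:]) / 2.0
        pdf = md.pairwise_distance_density(centers, r0=r0, sigma=sigma)
        out[(r0, sigma)] = float(np.abs(pdf - hist).max() / hist.max())
    return out
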
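"""Distribution-similarity metrics and the statistical testing battery.

Similarity between a "real" and a "synthetic" sample of scalar distances is
quantified three ways: Wasserstein-1 distance (integral of |F1 - F2|),
normalized MSE between density-normalized histograms (MSE over the variance
of the real PDF's bin values), and the Kolmogorov-Smirnov statistic
(sup |F1 - F2|).  Group comparisons use the Mann-Whitney U test (exact
enumeration for small groups, normal approximation with tie correction
otherwise), Benjamini-Hochberg FDR correction, and Cohen's D effect sizes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import MetricUndefinedError


def _check_sample(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name} sample is empty")
    return x


def wasserstein_distance(sample_a, sample_b) -> float:
    """1D Wasserstein-1 distance: integral of |F1(x) - F2(x)| dx."""
    a = _check_sample(sample_a, "first")
    b = _check_sample(sample_b, "second")
    return float(stats.wasserstein_distance(a, b))


def ks_statistic(sample_a, sample_b) -> float:
    """Kolmogorov-Smirnov statistic: sup_x |F1(x) - F2(x)|."""
    a = _check_sample(sample_a, "first")
    b = _check_sample(sample_b, "second")
    return float(stats.ks_2samp(a, b).statistic)


def shared_bin_edges(sample_a, sample_b, min_bins: int = 20) -> np.ndarray:
    """Freedman-Diaconis edges on the merged sample, with at least
    ``min_bins`` bins (NMSE is binning-sensitive, so both samples share them).
    """
    merged = np.concatenate([_check_sample(sample_a, "first"),
                             _check_sample(sample_b, "second")])
    lo, hi = merged.min(), merged.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.histogram_bin_edges(merged, bins="fd", range=(lo, hi))
    if len(edges) - 1 < min_bins:
        edges = np.linspace(lo, hi, min_bins + 1)
    return edges


def normalized_mse(sample_real, sample_synth, bin_edges=None) -> float:
    """MSE between the two density-normalized histograms divided by the
    population variance of the real PDF's bin values (asymmetric in its
    arguments by construction)."""
    real = _check_sample(sample_real, "real")
    synth = _check_sample(sample_synth, "synthetic")
    if bin_edges is None:
        bin_edges = shared_bin_edges(real, synth)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) < 3:
        raise ValueError("need at least 2 bins")
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    p_real, _ = np.histogram(real, bins=bin_edges, density=True)
    p_synth, _ = np.histogram(synth, bins=bin_edges, density=True)
    var = p_real.var()  # population variance of the binned real-PDF values
    if var == 0:
        raise MetricUndefinedError("flat real PDF (zero variance)", "nmse:flat-real-pdf")
    return float(np.mean((p_real - p_synth) ** 2) / var)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2.0


def mann_whitney_u(sample_a, sample_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test with midrank ties.

    Exact enumeration of all rank assignments when both groups have <= 8
    observations; otherwise the normal approximation with tie correction and
    continuity correction.  Returns (U of the first sample, p-value).
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError("alternative must be two-sided, less or greater")
    a = _check_sample(sample_a, "first")
    b = _check_sample(sample_b, "second")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    U = _u_from_ranks(ranks[:n_a].sum(), n_a)
    if max(n_a, n_b) <= 8:
        # enumerate every assignment of n_a of the pooled ranks to group a
        total = 0
        n_le = 0
        n_ge = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_from_ranks(ranks[list(idx)].sum(), n_a)
            total += 1
            n_le += u <= U + 1e-12
            n_ge += u >= U - 1e-12
        if alternative == "less":
            p = n_le / total
        elif alternative == "greater":
            p = n_ge / total
        else:
            p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return float(U), float(p)
    mu = n_a * n_b / 2.0
    N = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var = n_a * n_b / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return float(U), 1.0
    if alternative == "two-sided":
        z = (abs(U - mu) - 0.5) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (U - mu - 0.5) / np.sqrt(var)
        p = stats.norm.sf(z)
    else:
        z = (U - mu + 0.5) / np.sqrt(var)
        p = stats.norm.cdf(z)
    return float(U), float(min(p, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(sample_a, sample_b) -> float:
    """(mean_a - mean_b) / pooled SD with (n-1)-denominator sample variances."""
    a = _check_sample(sample_a, "first")
    b = _check_sample(sample_b, "second")
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        raise MetricUndefinedError("zero pooled variance", "cohens_d:zero-variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# real vs model distribution comparison
# ---------------------------------------------------------------------------

def compare_real_vs_model(real_spot_sets, model_spot_sets,
                          min_bins: int = 20) -> pd.DataFrame:
    """Wasserstein, normalized MSE and KS for the pooled pairwise-distance and
    pooled centered radial-distance distributions of two spot-set collections.

    Binning for the NMSE is shared, computed from the merged real+model
    sample.  Rows: 'pairwise', 'radial'.
    """
    from .models import _pool_pairwise, _pool_radii

    real = list(real_spot_sets)
    model = list(model_spot_sets)
    if not real or not model:
        raise ValueError("both collections must be nonempty")
    rows = {}
    for name, fn in (("pairwise", _pool_pairwise), ("radial", _pool_radii)):
        ra, mo = fn(real), fn(model)
        edges = shared_bin_edges(ra, mo, min_bins=min_bins)
        rows[name] = {
            "wasserstein": wasserstein_distance(ra, mo),
            "normalized_mse": normalized_mse(ra, mo, edges),
            "ks": ks_statistic(ra, mo),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
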
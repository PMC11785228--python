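"""Benchmark pipelines: metric sensitivity, spot-removal robustness,
condition comparison, and the centered-overlay doughnut analysis.

The sensitivity benchmark simulates replicate nuclei from each generator
(sweeping the covariance grid for the Gaussian-family patterns), computes the
per-nucleus metric table, and tests every non-CSR pattern against the CSR
reference per metric (Mann-Whitney U, Benjamini-Hochberg FDR across the
pattern family within each metric, absolute Cohen's D).

The robustness experiment removes k = 1..30 spots at random from each
46-spot nucleus and reports the percent change of each metric's mean value
relative to the 46-spot baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import simulators
from .core_io import NucleusGeometry, SpotSet, default_circle, rng_for
from .compare_stats import bh_fdr, cohens_d, mann_whitney_u
from .metrics import (
    METRIC_COLUMNS,
    GraphConfig,
    MetricUndefinedError,
    RipleyConfig,
    _metric_row,
)
from .models import FitError

#: metric columns compared in benchmark runs (six metrics + count/density)
DEFAULT_METRICS = METRIC_COLUMNS


@dataclass
class BenchmarkResult:
    """Per-nucleus metric values plus per (pattern x metric) tests vs CSR."""

    metrics: pd.DataFrame          # one row per nucleus, 'pattern' column
    tests: pd.DataFrame            # pattern, metric, U, p, p_adj, significant, cohens_d
    n_replicates: int = 0
    seed: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric per pattern."""
        num = self.metrics.select_dtypes(float)
        return self.metrics.groupby("pattern")[num.columns].agg(["mean", "std"])


@dataclass
class RobustnessCurve:
    """Mean metric value per (pattern, removal count) and percent change."""

    means: pd.DataFrame            # index (pattern, n_removed), metric columns
    percent_change: pd.DataFrame   # same shape, k=0 row is 0 by definition
    reasons: pd.DataFrame | None = None


def _generate_cohort(
    pattern: str,
    n_replicates: int,
    seed: int,
    pattern_index: int,
    geometry: NucleusGeometry,
    sweep_covariance: bool = True,
    n_spots: int = 46,
) -> list[SpotSet]:
    """Replicates of one generator; Gaussian-family patterns cycle through the
    covariance grid (20 sizes x 8 orientations)."""
    grid = simulators.covariance_grid() if sweep_covariance else None
    out = []
    for k in range(n_replicates):
        rng = rng_for(seed, pattern_index, k)
        if pattern in simulators.GAUSSIAN_FAMILY and grid is not None:
            size, theta = grid[k % len(grid)]
            spec = simulators.PatternSpec(
                name=pattern, n_spots=n_spots,
                covariance_size=size, covariance_orientation=theta,
            )
        else:
            spec = simulators.PatternSpec(name=pattern, n_spots=n_spots)
        out.append(
            simulators.generate(spec, geometry, rng, nucleus_id=f"{pattern}-{k:05d}")
        )
    return out


def _pattern_tests(df: pd.DataFrame, metric_cols, reference: str) -> pd.DataFrame:
    """MWU + BH-FDR (across patterns within each metric) + |Cohen's D|."""
    patterns = [p for p in df["pattern"].unique() if p != reference]
    ref_rows = df[df["pattern"] == reference]
    records = []
    for metric in metric_cols:
        ref_vals = ref_rows[metric].dropna().to_numpy()
        raw = []
        for pat in patterns:
            vals = df.loc[df["pattern"] == pat, metric].dropna().to_numpy()
            if len(vals) < 2 or len(ref_vals) < 2:
                records.append((pat, metric, np.nan, np.nan, np.nan))
                raw.append(np.nan)
                continue
            U, p = mann_whitney_u(vals, ref_vals)
            try:
                d = abs(cohens_d(vals, ref_vals))
            except MetricUndefinedError:
                d = 0.0
            records.append((pat, metric, U, p, d))
            raw.append(p)
        # BH correction across the pattern-vs-reference family for this metric
        raw = np.asarray(raw, dtype=float)
        ok = np.isfinite(raw)
        adj = np.full_like(raw, np.nan)
        if ok.any():
            adj[ok] = bh_fdr(raw[ok])
        base = len(records) - len(patterns)
        for i in range(len(patterns)):
            records[base + i] = records[base + i] + (adj[i],)
    out = pd.DataFrame(
        records, columns=["pattern", "metric", "U", "p", "cohens_d", "p_adj"]
    )
    out["significant"] = out["p_adj"] < 0.05
    return out[["pattern", "metric", "U", "p", "p_adj", "significant", "cohens_d"]]


def run_benchmark(
    patterns: Sequence[str] = simulators.PATTERN_NAMES,
    n_replicates: int = 1000,
    seed: int = 0,
    metric_columns: Sequence[str] = DEFAULT_METRICS,
    geometry: NucleusGeometry | None = None,
    ripley_cfg: RipleyConfig | None = None,
    graph_cfg: GraphConfig | None = None,
    reference: str = "CSR",
) -> BenchmarkResult:
    """Metric-sensitivity benchmark: replicate cohorts per pattern, per-nucleus
    metrics, and tests of every pattern against the CSR reference."""
    if reference not in patterns:
        raise ValueError(f"reference pattern {reference!r} must be among the patterns")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    geometry = geometry or default_circle()
    ripley_cfg = ripley_cfg or RipleyConfig()
    graph_cfg = graph_cfg or GraphConfig()
    rows = []
    for pi, pattern in enumerate(patterns):
        cohort = _generate_cohort(pattern, n_replicates, seed, pi, geometry)
        for ss in cohort:
            row, _ = _metric_row(ss, ripley_cfg, graph_cfg, seed, "per-axis",
                                 columns=metric_columns)
            row["pattern"] = pattern
            row["nucleus_id"] = ss.nucleus_id
            rows.append(row)
    df = pd.DataFrame(rows).set_index("nucleus_id")
    tests = _pattern_tests(df, metric_columns, reference)
    return BenchmarkResult(metrics=df, tests=tests, n_replicates=n_replicates, seed=seed)


def run_spot_removal(
    patterns: Sequence[str] = simulators.PATTERN_NAMES,
    n_replicates: int = 1000,
    removal_counts: Sequence[int] = tuple(range(1, 31)),
    seed: int = 0,
    metric_columns: Sequence[str] = DEFAULT_METRICS,
    geometry: NucleusGeometry | None = None,
    ripley_cfg: RipleyConfig | None = None,
    graph_cfg: GraphConfig | None = None,
    n_spots: int = 46,
) -> RobustnessCurve:
    """Spot-removal robustness: remove k spots uniformly at random from each
    nucleus, average each metric at each k, and report the percent change
    |mean_k - mean_0| / |mean_0| x 100 against the full-spot baseline.

    A zero baseline mean yields a missing percent change with reason
    'zero baseline' rather than an infinity.
    """
    removal_counts = sorted(set(int(k) for k in removal_counts))
    if any(k < 0 or k >= n_spots for k in removal_counts):
        raise ValueError(f"removal counts must lie in [0, {n_spots - 1}]")
    geometry = geometry or default_circle()
    ripley_cfg = ripley_cfg or RipleyConfig()
    graph_cfg = graph_cfg or GraphConfig()
    ks = [0] + [k for k in removal_counts if k != 0]
    sums = {}
    counts = {}
    for pi, pattern in enumerate(patterns):
        cohort = _generate_cohort(pattern, n_replicates, seed, pi, geometry,
                                  n_spots=n_spots)
        for col in metric_columns:
            for k in ks:
                sums[(pattern, k, col)] = 0.0
                counts[(pattern, k, col)] = 0
        for ri, ss in enumerate(cohort):
            rng = rng_for(seed, 1_000 + pi, ri)  # removal stream, separate from generation
            for k in ks:
                if k == 0:
                    sub = ss
                else:
                    keep = rng.choice(ss.n, ss.n - k, replace=False)
                    sub = SpotSet(ss.nucleus_id, ss.points[keep], ss.geometry,
                                  pattern=ss.pattern)
                row, _ = _metric_row(sub, ripley_cfg, graph_cfg, seed, "per-axis",
                                     columns=metric_columns)
                for col in metric_columns:
                    v = row[col]
                    if np.isfinite(v):
                        sums[(pattern, k, col)] += v
                        counts[(pattern, k, col)] += 1
    index = pd.MultiIndex.from_product([patterns, ks], names=["pattern", "n_removed"])
    means = pd.DataFrame(index=index, columns=list(metric_columns), dtype=float)
    for (pattern, k, col), s in sums.items():
        c = counts[(pattern, k, col)]
        means.loc[(pattern, k), col] = s / c if c else np.nan
    pc = pd.DataFrame(index=index, columns=list(metric_columns), dtype=float)
    reasons = pd.DataFrame("", index=index, columns=list(metric_columns))
    for pattern in patterns:
        base = means.loc[(pattern, 0)]
        for k in ks:
            for col in metric_columns:
                b = base[col]
                m = means.loc[(pattern, k), col]
                if not np.isfinite(b) or b == 0.0:
                    pc.loc[(pattern, k), col] = np.nan
                    reasons.loc[(pattern, k), col] = "zero baseline"
                elif np.isfinite(m):
                    pc.loc[(pattern, k), col] = abs(m - b) / abs(b) * 100.0
    return RobustnessCurve(means=means, percent_change=pc, reasons=reasons)


def compare_conditions(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame) -> pd.DataFrame:
    """Per-metric comparison of two per-nucleus metric tables (e.g. control vs
    perturbation): MWU, BH-FDR across the shared metric columns, |Cohen's D|,
    ranked by effect size."""
    cols = [
        c
        for c in metrics_a.columns
        if c in metrics_b.columns
        and pd.api.types.is_numeric_dtype(metrics_a[c])
        and pd.api.types.is_numeric_dtype(metrics_b[c])
    ]
    if not cols:
        raise ValueError("metric tables share no numeric metric columns")
    records = []
    for col in cols:
        a = metrics_a[col].dropna().to_numpy()
        b = metrics_b[col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            records.append((col, np.nan, np.nan, np.nan))
            continue
        U, p = mann_whitney_u(a, b)
        try:
            d = abs(cohens_d(a, b))
        except MetricUndefinedError:
            d = 0.0
        records.append((col, U, p, d))
    df = pd.DataFrame(records, columns=["metric", "U", "p", "cohens_d"])
    raw = df["p"].to_numpy()
    ok = np.isfinite(raw)
    adj = np.full_like(raw, np.nan)
    if ok.any():
        adj[ok] = bh_fdr(raw[ok])
    df["p_adj"] = adj
    df["significant"] = df["p_adj"] < 0.05
    df = df.sort_values("cohens_d", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["metric", "U", "p", "p_adj", "significant", "cohens_d", "rank"]]


# ---------------------------------------------------------------------------
# centered overlay and marginal Gaussian-mixture fit
# ---------------------------------------------------------------------------

def overlay_centered_spots(spot_sets, bins: int = 64, extent: float | None = None) -> dict:
    """Translate every nucleus's spots so its center sits at (0, 0), histogram
    all spots on symmetric 2D bins, and extract the central x=0 / y=0 line
    profiles."""
    spot_sets = list(spot_sets)
    if len(spot_sets) < 10:
        raise ValueError("overlay needs at least 10 nuclei")
    shifted = np.vstack(
        [ss.points - np.asarray(ss.geometry.center) for ss in spot_sets]
    )
    if extent is None:
        extent = max(ss.geometry.equivalent_radius for ss in spot_sets)
    H, xe, ye = np.histogram2d(
        shifted[:, 0], shifted[:, 1], bins=bins, range=[[-extent, extent]] * 2
    )
    c = bins // 2  # bin row/column nearest the center
    centers = (xe[:-1] + xe[1:]) / 2.0
    return {
        "hist": H,
        "x_edges": xe,
        "y_edges": ye,
        "bin_centers": centers,
        # profile along x at y ~ 0, and along y at x ~ 0
        "profile_x": H[:, c],
        "profile_y": H[c, :],
        "n_spots": int(H.sum()),
    }


def _gmm2(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-((x - m1) ** 2) / (2 * s1**2)) + a2 * np.exp(
        -((x - m2) ** 2) / (2 * s2**2)
    )


def fit_marginal_gmm_2mode(bin_centers, profile) -> dict:
    """Least-squares fit of a two-component 1D Gaussian mixture to a binned
    line profile; returns the parameters, the Pearson correlation between the
    fitted curve and the profile, and a degeneracy flag when the two modes
    collapse within one bin."""
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(profile, dtype=float)
    if x.size < 10:
        raise ValueError("profile needs at least 10 bins")
    bin_w = float(np.median(np.diff(x)))
    peak = max(y.max(), 1.0)
    half = x.size // 2
    left_peak = x[:half][np.argmax(y[:half])] if y[:half].max() > 0 else -abs(x).max() / 2
    right_peak = x[half:][np.argmax(y[half:])] if y[half:].max() > 0 else abs(x).max() / 2
    spread = max(abs(x).max() / 6.0, bin_w)
    p0 = [peak, left_peak, spread, peak, right_peak, spread]
    lo = [0.0, x.min(), bin_w / 10.0, 0.0, x.min(), bin_w / 10.0]
    hi = [np.inf, x.max(), np.ptp(x), np.inf, x.max(), np.ptp(x)]
    try:
        popt, _ = optimize.curve_fit(_gmm2, x, y, p0=p0, bounds=(lo, hi), maxfev=20_000)
    except RuntimeError as exc:
        resid = float(np.sqrt(np.mean((_gmm2(x, *p0) - y) ** 2)))
        raise FitError(f"2-mode GMM fit did not converge (rmse at start {resid:.3g})") from exc
    a1, m1, s1, a2, m2, s2 = popt
    if m2 < m1:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    fitted = _gmm2(x, a1, m1, s1, a2, m2, s2)
    corr = float(stats.pearsonr(fitted, y).statistic)
    w1 = a1 * s1
    w2 = a2 * s2
    wsum = w1 + w2 if (w1 + w2) > 0 else 1.0
    return {
        "means": (float(m1), float(m2)),
        "sigmas": (float(s1), float(s2)),
        "weights": (float(w1 / wsum), float(w2 / wsum)),
        "amplitudes": (float(a1), float(a2)),
        "correlation": corr,
        "degenerate": bool(abs(m2 - m1) < bin_w),
        "rmse": float(np.sqrt(np.mean((fitted - y) ** 2))),
    }
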
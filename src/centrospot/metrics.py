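"""Per-nucleus spot clustering metrics.

Six metrics quantify clustering of one nucleus's spots, plus spot number and
density:

* ``ripley_k_score`` -- percentage of evaluation radii where the (uncorrected)
  Ripley K estimate K(r) = (A/N^2) sum_{i!=j} I(d_ij <= r) exceeds the Poisson
  expectation pi r^2.
* ``assortativity`` -- edge-wise correlation of weighted node degrees
  (k_i = sum over incident edges of 1/d^2) on the k-nearest-neighbor graph.
* ``modularity`` -- Louvain partition quality Q of the 1/d^2-weighted k-NN
  graph.
* ``morans_i`` -- spatial autocorrelation of the coordinates themselves, with
  inverse-squared-distance weights; computed per axis and averaged.
* ``mnnd`` -- mean nearest-neighbor distance.
* ``dispersion_index`` -- population variance of pairwise distances over their
  mean.

Metrics that are undefined for a configuration (too few spots, edgeless graph,
zero variance) raise :class:`MetricUndefinedError`;
:func:`compute_metric_table` records these as missing values with a reason
code instead of dropping the nucleus.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import SpotSet

#: distance floor for 1/d^2 weights when two spots (nearly) coincide, pixels
COINCIDENT_EPS = 1e-6


class MetricUndefinedError(ValueError):
    """The metric is not defined for this spot configuration."""

    def __init__(self, message: str, code: str):
        super().__init__(message)
        self.code = code


@dataclass
class RipleyConfig:
    """Evaluation grid for the Ripley K score.

    ``r_max`` defaults to the nucleus circle (equivalent) radius; the grid is
    ``n_steps`` evenly spaced radii in (0, r_max] (r = 0 is uninformative).
    The printed estimator carries no edge correction, so none is applied.
    """

    r_max: float | None = None
    n_steps: int = 50

    def __post_init__(self) -> None:
        if self.r_max is not None and self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")

    def radii(self, geometry) -> np.ndarray:
        r_max = self.r_max if self.r_max is not None else geometry.equivalent_radius
        return np.linspace(0.0, r_max, self.n_steps + 1)[1:]


@dataclass
class GraphConfig:
    """k-NN graph construction: edge if either endpoint lists the other among
    its k nearest (union rule); weights for degrees are 1/d^2."""

    k_neighbors: int = 10

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


# ---------------------------------------------------------------------------
# internal helpers operating on raw coordinate arrays
# ---------------------------------------------------------------------------

def _dist_matrix(points: np.ndarray) -> np.ndarray:
    return squareform(pdist(points))


def _knn_edges(dmat: np.ndarray, k: int) -> np.ndarray:
    """Undirected union-rule k-NN edge list, shape (m, 2), i < j."""
    n = len(dmat)
    order = np.argsort(dmat, axis=1, kind="stable")
    nn = order[:, 1 : k + 1]  # skip self at distance 0
    src = np.repeat(np.arange(n), k)
    dst = nn.ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    return np.unique(np.column_stack([lo, hi]), axis=0)


def _weighted_degrees(dmat: np.ndarray, edges: np.ndarray) -> np.ndarray:
    n = len(dmat)
    d = np.maximum(dmat[edges[:, 0], edges[:, 1]], COINCIDENT_EPS)
    w = 1.0 / d**2
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], w)
    np.add.at(deg, edges[:, 1], w)
    return deg


def _ripley_score(points, geometry, cfg: RipleyConfig) -> float:
    n = len(points)
    radii = cfg.radii(geometry)
    d = pdist(points)
    # K(r) = A/N^2 * #ordered pairs within r; condensed distances count each pair once
    counts = np.searchsorted(np.sort(d), radii, side="right") * 2
    K = geometry.area / n**2 * counts
    return float(100.0 * np.mean(K - np.pi * radii**2 > 0))


def _assortativity(dmat: np.ndarray, edges: np.ndarray) -> float:
    deg = _weighted_degrees(dmat, edges)
    # each undirected edge contributes both endpoint orderings
    x = np.concatenate([deg[edges[:, 0]], deg[edges[:, 1]]])
    y = np.concatenate([deg[edges[:, 1]], deg[edges[:, 0]]])
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom < 1e-300 or np.isclose(np.var(deg), 0.0, atol=1e-24):
        return 0.0  # zero-variance convention
    r = float((xc * (y - y.mean())).sum() / denom)
    return float(np.clip(r, -1.0, 1.0))


def _modularity(dmat: np.ndarray, edges: np.ndarray, n: int, seed: int) -> float:
    d = np.maximum(dmat[edges[:, 0], edges[:, 1]], COINCIDENT_EPS)
    w = list(1.0 / d**2)
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges])
    # igraph's multilevel refinement consults the global RNG; pin it per call
    ig.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(weights=w)
    return float(g.modularity(part, weights=w))


def _morans_axis(values: np.ndarray, w: np.ndarray, W: float) -> float | None:
    dev = values - values.mean()
    denom = (dev**2).sum()
    if denom < 1e-300:
        return None
    return float(len(values) / W * (dev @ w @ dev) / denom)


def _morans(points: np.ndarray, dmat: np.ndarray, mode: str) -> float:
    n = len(points)
    d = np.maximum(dmat, COINCIDENT_EPS)
    w = 1.0 / d**2
    np.fill_diagonal(w, 0.0)
    W = w.sum()
    if mode == "per-axis":
        vals = [_morans_axis(points[:, ax], w, W) for ax in (0, 1)]
        vals = [v for v in vals if v is not None]
        if not vals:
            raise MetricUndefinedError(
                "all points identical on both axes", "morans_i:zero-variance"
            )
        out = float(np.mean(vals))
    elif mode == "dot":
        dev = points - points.mean(axis=0)
        denom = (dev**2).sum()
        if denom < 1e-300:
            raise MetricUndefinedError(
                "all points identical on both axes", "morans_i:zero-variance"
            )
        out = float(n / W * np.einsum("ia,ij,ja->", dev, w, dev) / denom)
    else:
        raise ValueError("morans mode must be 'per-axis' or 'dot'")
    if abs(out) > 1.0 and abs(out) - 1.0 < 1e-9:
        out = float(np.sign(out))
    return out


# ---------------------------------------------------------------------------
# public per-SpotSet metrics
# ---------------------------------------------------------------------------

def ripley_k_score(spots: SpotSet, cfg: RipleyConfig | None = None) -> float:
    """Percentage of grid radii where K(r) strictly exceeds pi r^2."""
    if spots.n < 2:
        raise MetricUndefinedError("Ripley K needs >= 2 spots", "ripley_k_score:n<2")
    return _ripley_score(spots.points, spots.geometry, cfg or RipleyConfig())


def assortativity(spots: SpotSet, cfg: GraphConfig | None = None) -> float:
    """Edge-wise correlation of inverse-squared-distance weighted degrees."""
    cfg = cfg or GraphConfig()
    if spots.n <= cfg.k_neighbors:
        raise MetricUndefinedError(
            f"needs more than k={cfg.k_neighbors} spots", "assortativity:n<=k"
        )
    dmat = _dist_matrix(spots.points)
    return _assortativity(dmat, _knn_edges(dmat, cfg.k_neighbors))


def modularity(spots: SpotSet, cfg: GraphConfig | None = None, seed: int = 0) -> float:
    """Louvain modularity Q of the k-NN graph with 1/d^2 edge weights
    (seeded); the same weighting the other graph metrics use."""
    cfg = cfg or GraphConfig()
    if spots.n < 3:
        raise MetricUndefinedError("modularity needs >= 3 spots", "modularity:n<3")
    k = min(cfg.k_neighbors, spots.n - 1)
    dmat = _dist_matrix(spots.points)
    edges = _knn_edges(dmat, k)
    if len(edges) == 0:
        raise MetricUndefinedError("k-NN graph has no edges", "modularity:edgeless")
    return _modularity(dmat, edges, spots.n, seed)


def morans_i(spots: SpotSet, mode: str = "per-axis") -> float:
    """Moran's I of the spot coordinates with w_ij = 1/d_ij^2.

    ``mode='per-axis'`` (default) applies the scalar formula to the x then the
    y coordinates and averages; ``mode='dot'`` uses the sum of centered
    coordinate dot products.
    """
    if spots.n < 2:
        raise MetricUndefinedError("Moran's I needs >= 2 spots", "morans_i:n<2")
    return _morans(spots.points, _dist_matrix(spots.points), mode)


def mnnd(spots: SpotSet) -> float:
    """Mean distance from each spot to its nearest other spot."""
    if spots.n < 2:
        raise MetricUndefinedError("MNND needs >= 2 spots", "mnnd:n<2")
    dmat = _dist_matrix(spots.points)
    np.fill_diagonal(dmat, np.inf)
    return float(dmat.min(axis=1).mean())


def dispersion_index(spots: SpotSet) -> float:
    """Population variance of pairwise distances divided by their mean."""
    if spots.n < 2:
        raise MetricUndefinedError(
            "dispersion index needs >= 2 spots", "dispersion_index:n<2"
        )
    d = pdist(spots.points)
    mu = d.mean()
    if mu == 0.0:
        raise MetricUndefinedError(
            "all spots coincident", "dispersion_index:zero-mean-distance"
        )
    return float(d.var() / mu)


def spot_density(spots: SpotSet) -> float:
    """Spots per pixel^2 of nucleus area."""
    return spots.n / spots.geometry.area


METRIC_COLUMNS = (
    "ripley_k_score",
    "assortativity",
    "modularity",
    "morans_i",
    "mnnd",
    "dispersion_index",
    "spot_number",
    "spot_density",
)


def _metric_row(
    spots: SpotSet,
    ripley_cfg: RipleyConfig,
    graph_cfg: GraphConfig,
    seed: int,
    morans_mode: str,
    columns=METRIC_COLUMNS,
) -> tuple[dict, list[str]]:
    """One nucleus -> metric values + reason codes; distance matrix shared."""
    row: dict = {c: np.nan for c in columns}
    reasons: list[str] = []
    pts = spots.points
    n = spots.n
    dmat = _dist_matrix(pts) if n >= 2 else None

    def attempt(name, fn):
        if name not in columns:
            return
        try:
            row[name] = fn()
        except MetricUndefinedError as exc:
            reasons.append(exc.code)

    def _need2(code):
        raise MetricUndefinedError("needs >= 2 spots", code)

    attempt(
        "ripley_k_score",
        lambda: _ripley_score(pts, spots.geometry, ripley_cfg)
        if n >= 2
        else _need2("ripley_k_score:n<2"),
    )
    if "assortativity" in columns:
        if n > graph_cfg.k_neighbors:
            row["assortativity"] = _assortativity(
                dmat, _knn_edges(dmat, graph_cfg.k_neighbors)
            )
        else:
            reasons.append("assortativity:n<=k")
    if "modularity" in columns:
        if n >= 3:
            edges = _knn_edges(dmat, min(graph_cfg.k_neighbors, n - 1))
            if len(edges):
                row["modularity"] = _modularity(dmat, edges, n, seed)
            else:
                reasons.append("modularity:edgeless")
        else:
            reasons.append("modularity:n<3")
    if "morans_i" in columns:
        if n >= 2:
            try:
                row["morans_i"] = _morans(pts, dmat, morans_mode)
            except MetricUndefinedError as exc:
                reasons.append(exc.code)
        else:
            reasons.append("morans_i:n<2")
    if "mnnd" in columns:
        if n >= 2:
            dm = dmat.copy()
            np.fill_diagonal(dm, np.inf)
            row["mnnd"] = float(dm.min(axis=1).mean())
        else:
            reasons.append("mnnd:n<2")
    if "dispersion_index" in columns:
        if n >= 2:
            d = squareform(dmat)
            mu = d.mean()
            if mu > 0:
                row["dispersion_index"] = float(d.var() / mu)
            else:
                reasons.append("dispersion_index:zero-mean-distance")
        else:
            reasons.append("dispersion_index:n<2")
    if "spot_number" in columns:
        row["spot_number"] = n
    if "spot_density" in columns:
        row["spot_density"] = spot_density(spots)
    return row, reasons


def compute_metric_table(
    spot_sets,
    ripley_cfg: RipleyConfig | None = None,
    graph_cfg: GraphConfig | None = None,
    seed: int = 0,
    morans_mode: str = "per-axis",
) -> pd.DataFrame:
    """All eight metric columns for every nucleus.

    Metric-undefined cases are recorded as NaN with a reason code in the
    ``reason`` column, never silently dropped.  Deterministic given ``seed``
    (Louvain tie-breaking).
    """
    spot_sets = list(spot_sets)
    if not spot_sets:
        raise ValueError("need at least one SpotSet")
    ripley_cfg = ripley_cfg or RipleyConfig()
    graph_cfg = graph_cfg or GraphConfig()
    rows = []
    for ss in spot_sets:
        row, reasons = _metric_row(ss, ripley_cfg, graph_cfg, seed, morans_mode)
        row["nucleus_id"] = ss.nucleus_id
        if ss.pattern is not None:
            row["pattern"] = ss.pattern
        row["reason"] = ";".join(reasons)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("nucleus_id")
    ordered = [c for c in METRIC_COLUMNS if c in df.columns]
    tail = [c for c in df.columns if c not in METRIC_COLUMNS]
    return df[ordered + tail]
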
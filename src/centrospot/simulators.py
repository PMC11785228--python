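"""The nine synthetic spot-pattern generators.

Each generator places ``n_spots`` points inside a nucleus geometry (default:
circle of radius 46 px centered at (128, 128)):

* ``CSR`` -- complete spatial randomness (homogeneous Poisson process).
* ``PDS`` -- Poisson-disk sampling with a hard minimum inter-spot distance.
* ``UTA`` / ``UTHA`` -- uniform seeds with two/three adjacent spots: a subset
  of seeds each receives one/two closely placed companions (uniform shift per
  axis).
* ``S2DG`` / ``T2DG`` / ``TH2DG`` -- one-, two-, three-component 2D Gaussian
  mixtures with covariance Sigma = R(theta) diag(sx^2, sy^2) R(theta)^T.
* ``2DGNB`` / ``T2DGTNB`` -- Gaussian mixtures with nuclear-body exclusion
  discs carved out of the density (models spots surrounding nucleoli).

All samplers use draw-and-filter: candidate points are drawn from the parent
law and the first ``n_spots`` accepted points (inside the nucleus and outside
any exclusion body) are retained, in draw order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core_io import ConfigError, NucleusGeometry, SpotSet, default_circle

PATTERN_NAMES = (
    "CSR",
    "PDS",
    "UTA",
    "UTHA",
    "S2DG",
    "T2DG",
    "TH2DG",
    "2DGNB",
    "T2DGTNB",
)

#: Gaussian-family patterns whose covariance is swept on the benchmark grid
GAUSSIAN_FAMILY = ("S2DG", "T2DG", "TH2DG", "2DGNB", "T2DGTNB")

#: candidate draws allowed per requested spot before a sampler gives up
REJECTION_BUDGET_FACTOR = 10_000


class PackingError(RuntimeError):
    """Poisson-disk (or exclusion) sampling could not place all spots."""

    def __init__(self, message: str, n_placed: int):
        super().__init__(message)
        self.n_placed = n_placed


@dataclass
class PatternSpec:
    """Generator name plus parameters.

    ``covariance_size`` is the Gaussian variance in pixels^2 (the paper sweeps
    50--1000); ``covariance_orientation`` rotates the principal axes;
    ``aspect`` is the sx^2 : sy^2 ratio (1 = isotropic, the default).
    Component means default to the printed arrangement relative to the
    geometry center: two modes at center +/- (0, 25); three modes at
    center + (0, -25), (0, +25), (-25, 0).
    """

    name: str
    n_spots: int = 46
    covariance_size: float = 200.0
    covariance_orientation: float = 0.0
    aspect: float = 1.0
    component_means: Sequence[tuple[float, float]] | None = None
    component_weights: Sequence[float] | None = None
    min_distance: float = 10.0
    n_perturbed: int = 15
    perturbation_range: tuple[float, float] = (-3.0, 3.0)
    body_centers: Sequence[tuple[float, float]] | None = None
    body_radii: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.name not in PATTERN_NAMES:
            raise ConfigError(
                f"unknown pattern {self.name!r}; valid names: {', '.join(PATTERN_NAMES)}"
            )
        if self.n_spots < 1:
            raise ConfigError("n_spots must be >= 1")
        if self.covariance_size <= 0:
            raise ConfigError("covariance_size must be positive")
        if self.min_distance <= 0:
            raise ConfigError("min_distance must be positive")
        if self.component_weights is not None:
            w = np.asarray(self.component_weights, dtype=float)
            if abs(w.sum() - 1.0) > 1e-12:
                raise ConfigError("component weights must sum to 1")


def covariance_grid(
    n_sizes: int = 20,
    n_orientations: int = 8,
    size_range: tuple[float, float] = (50.0, 1000.0),
) -> list[tuple[float, float]]:
    """The benchmark sweep: sizes evenly spaced in [50, 1000] px^2 crossed with
    orientations evenly spaced in [0, pi)."""
    sizes = np.linspace(*size_range, n_sizes)
    thetas = np.linspace(0.0, np.pi, n_orientations, endpoint=False)
    return [(float(s), float(t)) for s in sizes for t in thetas]


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _as_spotset(points, geometry, nucleus_id, pattern):
    return SpotSet(
        nucleus_id=nucleus_id, points=np.asarray(points, float), geometry=geometry,
        pattern=pattern,
    )


def _uniform_points(geometry: NucleusGeometry, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform over the geometry via bounding-box rejection."""
    xmin, xmax, ymin, ymax = geometry.bounding_box()
    out = np.empty((n, 2))
    m = 0
    budget = REJECTION_BUDGET_FACTOR * n
    drawn = 0
    while m < n:
        batch = max(n - m, 64)
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, batch), rng.uniform(ymin, ymax, batch)]
        )
        drawn += batch
        keep = cand[geometry.contains(cand)]
        take = min(len(keep), n - m)
        out[m : m + take] = keep[:take]
        m += take
        if drawn > budget:
            raise PackingError("uniform rejection budget exhausted", m)
    return out


def sample_uniform_in_circle(
    geometry: NucleusGeometry | None = None,
    n: int = 46,
    rng: np.random.Generator | None = None,
    nucleus_id: str = "sample",
) -> SpotSet:
    """CSR: points uniform on the bounding box, accepted iff inside the nucleus."""
    geometry = geometry or default_circle()
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = rng or np.random.default_rng()
    return _as_spotset(_uniform_points(geometry, n, rng), geometry, nucleus_id, "CSR")


def sample_poisson_disk(
    geometry: NucleusGeometry | None = None,
    n: int = 46,
    min_distance: float = 10.0,
    rng: np.random.Generator | None = None,
    candidate_budget: int | None = None,
    nucleus_id: str = "sample",
) -> SpotSet:
    """PDS: uniform candidates kept only if >= min_distance from all kept spots."""
    geometry = geometry or default_circle()
    rng = rng or np.random.default_rng()
    # area feasibility: n hard discs of radius min_distance/2 must fit
    if n * np.pi * (min_distance / 2.0) ** 2 > geometry.area:
        raise PackingError(
            f"{n} spots at min distance {min_distance} cannot pack into area "
            f"{geometry.area:.0f} px^2",
            0,
        )
    budget = candidate_budget or REJECTION_BUDGET_FACTOR * n
    pts = np.empty((n, 2))
    m = 0
    tries = 0
    d2 = min_distance**2
    while m < n and tries < budget:
        cand = _uniform_points(geometry, min(256, budget - tries), rng)
        for p in cand:
            tries += 1
            if m and (((pts[:m] - p) ** 2).sum(axis=1) < d2).any():
                continue
            pts[m] = p
            m += 1
            if m == n:
                break
    if m < n:
        raise PackingError(
            f"placed only {m}/{n} spots within the candidate budget ({budget})", m
        )
    return _as_spotset(pts, geometry, nucleus_id, "PDS")


def sample_adjacent_perturbed(
    geometry: NucleusGeometry | None = None,
    n: int = 46,
    n_perturbed: int = 15,
    adjacents_per_seed: int = 1,
    perturbation_range: tuple[float, float] = (-3.0, 3.0),
    rng: np.random.Generator | None = None,
    nucleus_id: str = "sample",
) -> SpotSet:
    """UTA (adjacents_per_seed=1) / UTHA (=2): uniform seeds, a subset of which
    spawn adjacent spots shifted by an independent uniform epsilon per axis.

    Seed count is n - n_perturbed * adjacents_per_seed so seeds plus adjacents
    total exactly n before the in-circle cap; the first n points inside the
    boundary are retained (topped up with uniform draws if adjacents escape).
    """
    if adjacents_per_seed not in (1, 2):
        raise ConfigError("adjacents_per_seed must be 1 (UTA) or 2 (UTHA)")
    geometry = geometry or default_circle()
    rng = rng or np.random.default_rng()
    n_seeds = n - n_perturbed * adjacents_per_seed
    if n_seeds < n_perturbed:
        raise ConfigError(
            f"n_perturbed={n_perturbed} needs at least {n_perturbed} of "
            f"{n_seeds} seeds"
        )
    seeds = _uniform_points(geometry, n_seeds, rng)
    lo, hi = perturbation_range
    ordered: list[np.ndarray] = []
    for i in range(n_seeds):
        ordered.append(seeds[i])
        if i < n_perturbed:
            for _ in range(adjacents_per_seed):
                ordered.append(seeds[i] + rng.uniform(lo, hi, 2))
    pts = np.asarray(ordered)
    pts = pts[geometry.contains(pts)][:n]
    if len(pts) < n:  # adjacents that left the nucleus: top up uniformly
        extra = _uniform_points(geometry, n - len(pts), rng)
        pts = np.vstack([pts, extra])
    pattern = "UTA" if adjacents_per_seed == 1 else "UTHA"
    return _as_spotset(pts, geometry, nucleus_id, pattern)


def build_covariance(size: float, theta: float, aspect: float = 1.0) -> np.ndarray:
    """Sigma = R(theta) diag(sx^2, sy^2) R(theta)^T with sx^2 = size,
    sy^2 = size / aspect."""
    if size <= 0 or aspect <= 0:
        raise ConfigError("covariance size and aspect must be positive")
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return R @ np.diag([size, size / aspect]) @ R.T


def sample_gaussian_mixture(
    geometry: NucleusGeometry | None = None,
    n: int = 46,
    components: Sequence[tuple] = (((128.0, 128.0), 200.0, 0.0),),
    weights: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    aspect: float = 1.0,
    nucleus_id: str = "sample",
    pattern: str | None = None,
) -> SpotSet:
    """S2DG / T2DG / TH2DG: draw from a 2D Gaussian mixture and keep the first
    n spots inside the nucleus boundary.

    ``components`` is a list of (mean, covariance_size, theta) tuples.
    """
    geometry = geometry or default_circle()
    rng = rng or np.random.default_rng()
    K = len(components)
    w = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float)
    if abs(w.sum() - 1.0) > 1e-12:
        raise ConfigError("mixture weights must sum to 1")
    means = np.asarray([c[0] for c in components], dtype=float)
    chols = []
    for _, size, theta in components:
        cov = build_covariance(size, theta, aspect)
        try:
            chols.append(np.linalg.cholesky(cov))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise ConfigError("covariance matrix is not positive definite") from exc
    out = np.empty((n, 2))
    m = 0
    drawn = 0
    budget = REJECTION_BUDGET_FACTOR * n
    while m < n:
        batch = max(4 * (n - m), 64)
        comp = rng.choice(K, size=batch, p=w)
        z = rng.standard_normal((batch, 2))
        cand = np.empty((batch, 2))
        for k in range(K):
            sel = comp == k
            cand[sel] = means[k] + z[sel] @ chols[k].T
        drawn += batch
        keep = cand[geometry.contains(cand)]
        take = min(len(keep), n - m)
        out[m : m + take] = keep[:take]
        m += take
        if drawn > budget:
            raise PackingError("Gaussian-mixture rejection budget exhausted", m)
    return _as_spotset(out, geometry, nucleus_id, pattern)


def apply_nuclear_body_exclusion(
    base_sampler: Callable[[int, np.random.Generator], np.ndarray],
    body_centers: Sequence[tuple[float, float]],
    body_radii: Sequence[float],
    n: int,
    rng: np.random.Generator,
    geometry: NucleusGeometry | None = None,
    nucleus_id: str = "sample",
    pattern: str | None = None,
) -> SpotSet:
    """Wrap any sampler with hard exclusion discs (nuclear bodies): candidate
    points inside any body are rejected and redrawn until n are retained.

    ``base_sampler(n, rng)`` must return an (n, 2) array of in-nucleus points.
    """
    geometry = geometry or default_circle()
    centers = np.asarray(body_centers, dtype=float)
    radii = np.asarray(body_radii, dtype=float)
    if len(centers) != len(radii):
        raise ConfigError("body_centers and body_radii must have equal length")
    if len(centers) and not geometry.contains(centers).all():
        raise ConfigError("nuclear-body discs must lie inside the nucleus geometry")
    out = np.empty((n, 2))
    m = 0
    rounds = 0
    while m < n:
        cand = np.asarray(base_sampler(n - m, rng), dtype=float)
        if len(radii):
            d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            cand = cand[~(d2 < radii[None, :] ** 2).any(axis=1)]
        take = min(len(cand), n - m)
        out[m : m + take] = cand[:take]
        m += take
        rounds += 1
        if rounds > REJECTION_BUDGET_FACTOR:
            raise PackingError(
                "nuclear-body exclusion rejected nearly all candidates "
                "(bodies cover the high-density region?)",
                m,
            )
    return _as_spotset(out, geometry, nucleus_id, pattern)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _default_means(name: str, center: np.ndarray) -> np.ndarray:
    if name in ("T2DG", "T2DGTNB"):
        return center + np.array([(0.0, -25.0), (0.0, 25.0)])
    if name == "TH2DG":
        return center + np.array([(0.0, -25.0), (0.0, 25.0), (-25.0, 0.0)])
    return center[None, :]


def generate(
    spec: PatternSpec,
    geometry: NucleusGeometry | None = None,
    rng: np.random.Generator | None = None,
    nucleus_id: str = "sample",
) -> SpotSet:
    """Generate one spot set from a :class:`PatternSpec`."""
    geometry = geometry or default_circle()
    rng = rng or np.random.default_rng()
    name = spec.name
    if name == "CSR":
        ss = sample_uniform_in_circle(geometry, spec.n_spots, rng, nucleus_id)
    elif name == "PDS":
        ss = sample_poisson_disk(
            geometry, spec.n_spots, spec.min_distance, rng, nucleus_id=nucleus_id
        )
    elif name in ("UTA", "UTHA"):
        ss = sample_adjacent_perturbed(
            geometry,
            spec.n_spots,
            spec.n_perturbed,
            1 if name == "UTA" else 2,
            spec.perturbation_range,
            rng,
            nucleus_id,
        )
    elif name in ("S2DG", "T2DG", "TH2DG"):
        center = np.asarray(geometry.center, float)
        means = (
            np.asarray(spec.component_means, float)
            if spec.component_means is not None
            else _default_means(name, center)
        )
        comps = [
            (tuple(mu), spec.covariance_size, spec.covariance_orientation) for mu in means
        ]
        ss = sample_gaussian_mixture(
            geometry,
            spec.n_spots,
            comps,
            spec.component_weights,
            rng,
            spec.aspect,
            nucleus_id,
            pattern=name,
        )
    elif name in ("2DGNB", "T2DGTNB"):
        center = np.asarray(geometry.center, float)
        base_name = "S2DG" if name == "2DGNB" else "T2DG"
        means = (
            np.asarray(spec.component_means, float)
            if spec.component_means is not None
            else _default_means(base_name, center)
        )
        comps = [
            (tuple(mu), spec.covariance_size, spec.covariance_orientation) for mu in means
        ]
        if spec.body_centers is not None:
            centers, radii = spec.body_centers, spec.body_radii
        elif name == "2DGNB":
            centers, radii = [tuple(center)], [15.0]
        else:
            centers, radii = [tuple(mu) for mu in means], [12.0, 12.0]

        def base(k: int, r: np.random.Generator) -> np.ndarray:
            return sample_gaussian_mixture(
                geometry, k, comps, spec.component_weights, r, spec.aspect
            ).points

        ss = apply_nuclear_body_exclusion(
            base, centers, radii, spec.n_spots, rng, geometry, nucleus_id, pattern=name
        )
    else:  # pragma: no cover - PatternSpec validates names
        raise ConfigError(
            f"unknown pattern {name!r}; valid names: {', '.join(PATTERN_NAMES)}"
        )
    ss.pattern = name
    return ss
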
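"""Domain types, spot-table and label-mask I/O, and the synthetic fixture generator.

Coordinate convention: 0-based pixel coordinates, ``(x, y) = (column, row)``,
no half-pixel offset.  Spot tables are CSV files with header
``nucleus_id,x,y``; extra columns are ignored (with a logged note).  Label
masks are 16-bit unsigned TIFFs, background 0, one integer label per nucleus.

The default nucleus is a circle of radius 46 px centered at (128, 128) on a
256x256 patch: a 10 micrometer diameter nucleus at 0.108 micron/pixel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage import measure

logger = logging.getLogger(__name__)

#: microns per pixel of the imaging system the defaults emulate
DEFAULT_PIXEL_SIZE = 0.108
#: side of the synthetic image patch, pixels
DEFAULT_PATCH_SIZE = 256
#: default synthetic nucleus: 10 um diameter at 0.108 um/px -> radius ~46 px
DEFAULT_RADIUS = 46.0
DEFAULT_CENTER = (128.0, 128.0)


class SpotTableFormatError(ValueError):
    """Spot table is missing a required column or has malformed rows."""


class MaskError(ValueError):
    """Label mask contains no usable nuclei."""


class ConfigError(ValueError):
    """Invalid simulator / pipeline configuration."""


@dataclass
class NucleusGeometry:
    """Circle, fitted-ellipse, or mask description of one nucleus.

    Parameters
    ----------
    kind : {"circle", "ellipse", "mask"}
    center : (cx, cy) in pixels, (x, y) = (column, row).
    radius : circle radius in pixels (circle kind).
    axes : full major/minor axis lengths (a, b) in pixels (ellipse kind).
    orientation : major-axis angle from the x axis, radians in [0, pi).
    area : nucleus area in pixels^2; derived for circle/ellipse, explicit
        (pixel count) for mask kind.
    """

    kind: str
    center: tuple[float, float]
    radius: float | None = None
    axes: tuple[float, float] | None = None
    orientation: float = 0.0
    area: float = 0.0
    pixel_size: float = DEFAULT_PIXEL_SIZE
    mask: np.ndarray | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "ellipse", "mask"):
            raise ConfigError(f"unknown geometry kind {self.kind!r}")
        if self.kind == "circle":
            if self.radius is None or self.radius <= 0:
                raise ConfigError("circle geometry requires a positive radius")
            expected = np.pi * self.radius**2
            if self.area == 0.0:
                self.area = expected
            elif not np.isclose(self.area, expected, rtol=1e-9):
                raise ConfigError("circle area inconsistent with A = pi r^2")
        elif self.kind == "ellipse":
            if self.axes is None or min(self.axes) <= 0:
                raise ConfigError("ellipse geometry requires positive axes (a, b)")
            expected = np.pi * self.axes[0] * self.axes[1] / 4.0
            if self.area == 0.0:
                self.area = expected
            elif not np.isclose(self.area, expected, rtol=1e-9):
                raise ConfigError("ellipse area inconsistent with A = pi (a/2)(b/2)")
            self.orientation = float(self.orientation) % np.pi
        else:  # mask
            if self.mask is None or self.label is None:
                raise ConfigError("mask geometry requires a mask array and a label")
            if self.area <= 0:
                self.area = float(np.count_nonzero(self.mask == self.label))
        if self.area <= 0:
            raise ConfigError("geometry area must be positive")

    @property
    def equivalent_radius(self) -> float:
        """Radius of the circle with the same area (used for Ripley's r_max)."""
        return float(np.sqrt(self.area / np.pi))

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the nucleus support."""
        cx, cy = self.center
        if self.kind == "circle":
            r = self.radius
            return cx - r, cx + r, cy - r, cy + r
        if self.kind == "ellipse":
            a2, b2 = self.axes[0] / 2.0, self.axes[1] / 2.0
            c, s = np.cos(self.orientation), np.sin(self.orientation)
            hx = np.hypot(a2 * c, b2 * s)
            hy = np.hypot(a2 * s, b2 * c)
            return cx - hx, cx + hx, cy - hy, cy + hy
        rows, cols = np.nonzero(self.mask == self.label)
        return cols.min() - 0.5, cols.max() + 0.5, rows.min() - 0.5, rows.max() + 0.5

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Boolean containment test for an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx = pts[:, 0] - self.center[0]
        dy = pts[:, 1] - self.center[1]
        if self.kind == "circle":
            return dx**2 + dy**2 <= self.radius**2 + atol
        if self.kind == "ellipse":
            c, s = np.cos(self.orientation), np.sin(self.orientation)
            u = dx * c + dy * s
            v = -dx * s + dy * c
            a2, b2 = self.axes[0] / 2.0, self.axes[1] / 2.0
            return (u / a2) ** 2 + (v / b2) ** 2 <= 1.0 + atol
        cols = np.round(pts[:, 0]).astype(int)
        rows = np.round(pts[:, 1]).astype(int)
        ok = (
            (rows >= 0)
            & (rows < self.mask.shape[0])
            & (cols >= 0)
            & (cols < self.mask.shape[1])
        )
        inside = np.zeros(len(pts), dtype=bool)
        inside[ok] = self.mask[rows[ok], cols[ok]] == self.label
        return inside

    def rasterize(self, shape: tuple[int, int] | None = None, label: int = 1) -> np.ndarray:
        """Filled 16-bit label image of the geometry."""
        if self.kind == "mask":
            return (self.mask == self.label).astype(np.uint16) * np.uint16(label)
        if shape is None:
            shape = (DEFAULT_PATCH_SIZE, DEFAULT_PATCH_SIZE)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        img = self.contains(pts).reshape(shape)
        return img.astype(np.uint16) * np.uint16(label)


def default_circle(
    radius: float = DEFAULT_RADIUS, center: tuple[float, float] = DEFAULT_CENTER
) -> NucleusGeometry:
    """The default synthetic nucleus geometry (circle r=46 px at (128, 128))."""
    return NucleusGeometry(kind="circle", center=center, radius=radius)


@dataclass
class SpotSet:
    """One nucleus's 2D spot coordinates plus its geometry.

    ``points`` is an (n, 2) float array of (x, y) pixel coordinates with the
    file/draw order preserved.
    """

    nucleus_id: str
    points: np.ndarray
    geometry: NucleusGeometry
    pattern: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("spot coordinates must be finite")
        self.points = pts

    @property
    def n(self) -> int:
        return len(self.points)

    def radii(self) -> np.ndarray:
        """Distances of each spot from the nucleus geometry center."""
        d = self.points - np.asarray(self.geometry.center)
        return np.hypot(d[:, 0], d[:, 1])


# ---------------------------------------------------------------------------
# spot tables
# ---------------------------------------------------------------------------

_REQUIRED = ("nucleus_id", "x", "y")


def read_spot_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    geometry: NucleusGeometry | Mapping[str, NucleusGeometry] | None = None,
) -> list[SpotSet]:
    """Read a CSV spot table into one :class:`SpotSet` per nucleus id.

    ``dialect`` maps the canonical column names (``nucleus_id``, ``x``, ``y``)
    to the file's column names.  If no geometry is supplied, each spot set gets
    the bounding circle of its own points.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path)
    cols = {name: dialect.get(name, name) for name in _REQUIRED}
    for canon, col in cols.items():
        if col not in df.columns:
            raise SpotTableFormatError(
                f"spot table {path} is missing required column {col!r} (for {canon!r})"
            )
    extra = set(df.columns) - set(cols.values())
    if extra:
        logger.info("ignoring extra spot-table columns: %s", sorted(extra))
    for canon in ("x", "y"):
        col = cols[canon]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpotTableFormatError(
                f"non-numeric {canon!r} value {df[col].iloc[row]!r} at data row {row}"
            )
        df[col] = coerced
    out: list[SpotSet] = []
    for nid, grp in df.groupby(cols["nucleus_id"], sort=False):
        pts = grp[[cols["x"], cols["y"]]].to_numpy(dtype=float)
        if isinstance(geometry, NucleusGeometry):
            geom = geometry
        elif geometry is not None and str(nid) in geometry:
            geom = geometry[str(nid)]
        else:
            geom = _bounding_circle(pts)
        out.append(SpotSet(nucleus_id=str(nid), points=pts, geometry=geom))
    return out


def _bounding_circle(points: np.ndarray) -> NucleusGeometry:
    """Circle covering all points: bbox midpoint center, max-distance radius."""
    if len(points) == 0:
        return default_circle()
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    center = (lo + hi) / 2.0
    radius = float(np.max(np.hypot(*(points - center).T)))
    return NucleusGeometry(
        kind="circle", center=tuple(center), radius=max(radius, 1.0)
    )


def write_spot_table(spot_sets: Iterable[SpotSet], path: str | Path) -> None:
    """Write spot sets to CSV (``nucleus_id,x,y``) with 6-decimal coordinates."""
    rows = []
    for ss in spot_sets:
        for x, y in ss.points:
            rows.append((ss.nucleus_id, x, y))
    df = pd.DataFrame(rows, columns=list(_REQUIRED))
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------

def extract_geometry_from_mask(mask: np.ndarray) -> list[NucleusGeometry]:
    """Fit an ellipse to every labeled region of a nucleus label mask.

    Per label: center = region centroid, (a, b) = full major/minor axis
    lengths of the second-moment-matched ellipse, orientation in [0, pi),
    area = pixel count.  Regions of fewer than 5 pixels are skipped with a
    warning (second moments are degenerate).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MaskError("label mask must be a 2D integer image")
    if not np.any(mask):
        raise MaskError("no nuclei: label mask is empty")
    out: list[NucleusGeometry] = []
    for region in measure.regionprops(mask.astype(np.int64)):
        if region.area < 5:
            warnings.warn(
                f"skipping label {region.label}: {region.area} px < 5 (moments degenerate)",
                stacklevel=2,
            )
            continue
        row_c, col_c = region.centroid
        # skimage orientation is measured from the row (0th) axis; convert to
        # the x-axis convention and wrap into [0, pi)
        theta = (np.pi / 2.0 - region.orientation) % np.pi
        out.append(
            NucleusGeometry(
                kind="ellipse",
                center=(col_c, row_c),
                axes=(region.axis_major_length, region.axis_minor_length),
                orientation=theta,
                area=np.pi * region.axis_major_length * region.axis_minor_length / 4.0,
                mask=None,
                label=int(region.label),
            )
        )
    if not out:
        raise MaskError("no nuclei: all regions were degenerate (< 5 px)")
    return out


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


# ---------------------------------------------------------------------------
# fixtures and seeding
# ---------------------------------------------------------------------------

def rng_for(seed: int, *counters: int) -> np.random.Generator:
    """Counter-derived random stream: replicate k is reproducible regardless of
    how many replicates a run requests."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=counters))


def make_fixture(
    pattern_specs: Sequence,
    n_replicates: int,
    seed: int,
    geometry: NucleusGeometry | None = None,
    masks_dir: str | Path | None = None,
) -> list[SpotSet]:
    """Generate synthetic spot sets from a list of pattern specifications.

    Deterministic given ``seed``; each spot set is tagged with the name of the
    generating pattern.  With ``masks_dir``, one 16-bit label TIFF containing
    the filled geometry is written per nucleus.
    """
    from . import simulators  # local import to avoid a cycle

    if n_replicates < 1:
        raise ConfigError("replicate count must be >= 1")
    geometry = geometry or default_circle()
    out: list[SpotSet] = []
    for si, spec in enumerate(pattern_specs):
        if isinstance(spec, str):
            spec = simulators.PatternSpec(name=spec)
        for k in range(n_replicates):
            rng = rng_for(seed, si, k)
            nucleus_id = f"{spec.name}-{k:05d}"
            ss = simulators.generate(spec, geometry=geometry, rng=rng, nucleus_id=nucleus_id)
            out.append(ss)
            if masks_dir is not None:
                Path(masks_dir).mkdir(parents=True, exist_ok=True)
                write_mask(geometry.rasterize(), Path(masks_dir) / f"{nucleus_id}.tif")
    return out


def load_config(path: str | Path) -> dict:
    """Load a flat key-value YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a flat key-value mapping")
    return cfg
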
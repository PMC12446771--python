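"""Core containers and geometric primitives for immunogold point patterns.

A membrane sheet is modelled as a rectangular observation window (nm units)
carrying one or two populations of gold-particle coordinates.  All radial
statistics in the package are functions of distance r on a 1-nm grid and are
stored as :class:`RadialCurve`; Monte Carlo null envelopes are stored as
:class:`NullEnvelope`.

Coordinate tables are delimited text (CSV/TSV) with a header row and columns
``image_id,x_nm,y_nm[,species][,win_xmin,win_xmax,win_ymin,win_ymax]``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, squareform, pdist

__all__ = [
    "GoldmapError",
    "PatternTableError",
    "InsufficientPointsError",
    "InsufficientSimulationsError",
    "GridMismatchError",
    "UndefinedCurveError",
    "DomainError",
    "SpatialWindow",
    "PointPattern",
    "BivariatePattern",
    "RadialCurve",
    "NullEnvelope",
    "default_grid",
    "bounding_window",
    "pairwise_distances",
    "toroidal_distance_matrix",
    "edge_weight",
    "isotropic_weights",
    "read_pattern_table",
    "write_pattern_table",
]

#: default evaluation grid, 1..240 nm in 1 nm steps
DEFAULT_R_MIN = 1.0
DEFAULT_R_MAX = 240.0


def default_grid(r_min: float = DEFAULT_R_MIN, r_max: float = DEFAULT_R_MAX) -> np.ndarray:
    """Distance grid in nm with unit spacing, endpoints included."""
    return np.arange(float(r_min), float(r_max) + 0.5, 1.0)


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class GoldmapError(Exception):
    """Base class for all package errors."""


class PatternTableError(GoldmapError, ValueError):
    """Malformed coordinate or prey table."""


class InsufficientPointsError(GoldmapError, ValueError):
    """Too few points for the requested estimator."""


class InsufficientSimulationsError(GoldmapError, ValueError):
    """Fewer Monte Carlo simulations than the enforced minimum."""


class GridMismatchError(GoldmapError, ValueError):
    """Curve and envelope evaluated on different distance grids."""


class UndefinedCurveError(GoldmapError, ValueError):
    """Operation requires defined (finite) curve values that are missing."""


class DomainError(GoldmapError, ValueError):
    """Argument outside the mathematical domain of an operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialWindow:
    """Rectangular observation window, lengths in nm."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise DomainError(
                f"degenerate window [{self.x_min},{self.x_max}]x[{self.y_min},{self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        """Window area A in nm^2."""
        return self.width * self.height

    @classmethod
    def square(cls, side: float, origin: float = 0.0) -> "SpatialWindow":
        return cls(origin, origin + side, origin, origin + side)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (pts[:, 0] >= self.x_min - tol)
            & (pts[:, 0] <= self.x_max + tol)
            & (pts[:, 1] >= self.y_min - tol)
            & (pts[:, 1] <= self.y_max + tol)
        )


@dataclass(frozen=True)
class PointPattern:
    """A single labelled population of gold-particle coordinates on one sheet.

    ``points`` is an (n, 2) float array of x/y coordinates in nm; every point
    must lie inside (or on the boundary of) ``window``.  Coincident points are
    legal: two particles can project to the same position.
    """

    window: SpatialWindow
    points: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and not np.all(np.isfinite(pts)):
            raise DomainError(f"non-finite coordinates in pattern {self.image_id!r}")
        if pts.size:
            inside = self.window.contains(pts)
            if not inside.all():
                bad = int(np.flatnonzero(~inside)[0])
                raise DomainError(
                    f"point {tuple(pts[bad])} outside window in pattern {self.image_id!r}"
                )

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class BivariatePattern:
    """Two gold-particle populations ("big" 6 nm / "small" 2 nm) on one sheet."""

    big: PointPattern
    small: PointPattern

    def __post_init__(self) -> None:
        if self.big.window != self.small.window:
            raise DomainError("big and small populations must share one window")
        if self.big.image_id != self.small.image_id:
            raise DomainError("big and small populations must share one image_id")

    @property
    def window(self) -> SpatialWindow:
        return self.big.window

    @property
    def image_id(self) -> str:
        return self.big.image_id

    @property
    def n_b(self) -> int:
        return self.big.n

    @property
    def n_s(self) -> int:
        return self.small.n


@dataclass(frozen=True)
class RadialCurve:
    """A function of distance r on a strictly increasing grid.

    ``kind`` is one of ``K``, ``L_minus_r``, ``K_biv``, ``L_biv_minus_r``,
    ``standardized``.  Undefined grid points are stored as NaN.
    """

    r: np.ndarray
    values: np.ndarray
    kind: str = "K"

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "values", v)
        if r.ndim != 1 or v.shape != r.shape:
            raise DomainError("r and values must be 1-d arrays of equal length")
        if r.size >= 2 and not np.all(np.diff(r) > 0):
            raise DomainError("r grid must be strictly increasing")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of grid points carrying a finite value."""
        return np.isfinite(self.values)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"r_nm": self.r, "value": self.values}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class NullEnvelope:
    """Pointwise Monte Carlo upper-percentile curve under a null model."""

    r: np.ndarray
    upper: np.ndarray
    percentile: float
    n_sim: int
    null_model: str
    seed: int | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        u = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "upper", u)
        if u.shape != r.shape:
            raise DomainError("upper and r must have equal length")
        if self.n_sim < 100:
            raise InsufficientSimulationsError(
                f"n_sim={self.n_sim} < 100 simulations required for a stable envelope"
            )

    def as_curve(self) -> RadialCurve:
        """The envelope itself viewed as a radial curve (for standardization)."""
        return RadialCurve(self.r, self.upper, kind="L_minus_r")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def bounding_window(points: np.ndarray) -> SpatialWindow:
    """Axis-aligned bounding box of the points (no expansion).

    Used only when a table supplies no explicit window; analyses should be
    given the true sheet window (typically 1000x1000 nm) whenever known.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 2:
        raise DomainError("need >= 2 points to derive a bounding window")
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 <= x0 or y1 <= y0:
        raise DomainError("degenerate bounding window (collinear coordinates)")
    return SpatialWindow(x0, x1, y0, y1)


def pairwise_distances(pattern: PointPattern) -> np.ndarray:
    """Symmetric Euclidean distance matrix in nm with zero diagonal."""
    if pattern.n == 0:
        return np.zeros((0, 0))
    if pattern.n == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pattern.points))


def toroidal_distance_matrix(
    a: np.ndarray, b: np.ndarray, window: SpatialWindow
) -> np.ndarray:
    """Distance matrix on the torus obtained by wrapping the window edges."""
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    dx = np.abs(a[:, None, 0] - b[None, :, 0])
    dy = np.abs(a[:, None, 1] - b[None, :, 1])
    dx = np.minimum(dx, window.width - dx)
    dy = np.minimum(dy, window.height - dy)
    return np.hypot(dx, dy)


def isotropic_weights(
    centers: np.ndarray, radii: np.ndarray, window: SpatialWindow
) -> np.ndarray:
    """Ripley isotropic edge-correction weights for a rectangular window.

    For each center and radius the weight is the reciprocal of the fraction of
    the circle's perimeter lying inside the window, computed in closed form
    from the distances to the four edges with corner overlaps removed.  Radius
    zero (coincident particles) carries weight 1.  Weights are >= 1 and equal
    1 for fully interior circles.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if centers.shape[0] != radii.shape[0]:
        raise DomainError("centers and radii must align")
    if np.any(radii < 0):
        raise DomainError("negative radius")

    d = np.where(radii > 0, radii, 1.0)  # dummy for r == 0, fixed at the end
    dl = centers[:, 0] - window.x_min
    dr = window.x_max - centers[:, 0]
    db = centers[:, 1] - window.y_min
    dt = window.y_max - centers[:, 1]

    def half_angle(e: np.ndarray) -> np.ndarray:
        # angle subtended outside one edge is 2*arccos(e/d); store the half
        return np.arccos(np.clip(e / d, -1.0, 1.0))

    hl, hr, hb, ht = half_angle(dl), half_angle(dr), half_angle(db), half_angle(dt)
    outside = 2.0 * (hl + hr + hb + ht)
    # adjacent edges overlap in the corner wedge when e1^2 + e2^2 < d^2
    for h1, h2 in ((hl, hb), (hb, hr), (hr, ht), (ht, hl)):
        outside -= np.maximum(h1 + h2 - 0.5 * math.pi, 0.0)
    frac_inside = np.clip(1.0 - outside / (2.0 * math.pi), 1e-12, 1.0)
    w = 1.0 / frac_inside
    w[radii == 0] = 1.0
    return w


def edge_weight(point: Sequence[float], distance: float, window: SpatialWindow) -> float:
    """Isotropic edge-correction weight for one circle (see isotropic_weights)."""
    if distance <= 0:
        raise DomainError(f"distance must be > 0, got {distance}")
    pt = np.asarray(point, dtype=float).reshape(1, 2)
    if not window.contains(pt)[0]:
        raise DomainError(f"point {tuple(pt[0])} outside window")
    return float(isotropic_weights(pt, np.array([distance]), window)[0])


# ---------------------------------------------------------------------------
# coordinate-table I/O
# ---------------------------------------------------------------------------

_WINDOW_COLS = ("win_xmin", "win_xmax", "win_ymin", "win_ymax")


def _species_magnitude(label: str) -> tuple:
    """Sort key for species labels: numeric prefix when present ('6nm' > '2nm')."""
    m = re.match(r"\s*([0-9]*\.?[0-9]+)", str(label))
    return (1, float(m.group(1))) if m else (0, str(label))


def read_pattern_table(
    path: str | Path,
) -> list[PointPattern] | list[BivariatePattern]:
    """Read a coordinate table into per-image patterns.

    Returns a list of :class:`PointPattern` (no ``species`` column) or
    :class:`BivariatePattern` (``species`` column with exactly two labels per
    image; the label with the larger numeric prefix is taken as the "big"
    population), ordered by first appearance of ``image_id``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in ("image_id", "x_nm", "y_nm"):
        if col not in df.columns:
            raise PatternTableError(f"{path.name}: missing required column {col!r}")

    numeric_cols = ["x_nm", "y_nm"] + [c for c in _WINDOW_COLS if c in df.columns]
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        missing = df.index[df[col].isna()]
        if len(bad):
            # +2: header line plus 1-based file rows
            raise PatternTableError(
                f"{path.name}: malformed value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at file row {int(bad[0]) + 2}"
            )
        if len(missing) and col in ("x_nm", "y_nm"):
            raise PatternTableError(
                f"{path.name}: missing coordinate in column {col!r} "
                f"at file row {int(missing[0]) + 2}"
            )
        df[col] = parsed

    have_window = [c for c in _WINDOW_COLS if c in df.columns]
    if have_window and len(have_window) != 4:
        raise PatternTableError(
            f"{path.name}: window bounds require all four columns {_WINDOW_COLS}"
        )
    has_species = "species" in df.columns

    patterns: list = []
    for image_id, grp in df.groupby("image_id", sort=False):
        if have_window:
            bounds = grp[list(_WINDOW_COLS)].drop_duplicates()
            if len(bounds) != 1:
                raise PatternTableError(
                    f"{path.name}: inconsistent window bounds within image {image_id!r}"
                )
            b = bounds.iloc[0]
            window = SpatialWindow(
                float(b.win_xmin), float(b.win_xmax), float(b.win_ymin), float(b.win_ymax)
            )
        else:
            window = bounding_window(grp[["x_nm", "y_nm"]].to_numpy())

        if has_species:
            labels = sorted(grp["species"].unique(), key=_species_magnitude)
            if len(labels) != 2:
                raise PatternTableError(
                    f"{path.name}: image {image_id!r} has species {labels}; "
                    "exactly two are required for a bivariate pattern"
                )
            small_lab, big_lab = labels
            sub = {
                lab: PointPattern(
                    window,
                    grp.loc[grp["species"] == lab, ["x_nm", "y_nm"]].to_numpy(),
                    image_id=str(image_id),
                )
                for lab in (big_lab, small_lab)
            }
            patterns.append(BivariatePattern(big=sub[big_lab], small=sub[small_lab]))
        else:
            patterns.append(
                PointPattern(
                    window, grp[["x_nm", "y_nm"]].to_numpy(), image_id=str(image_id)
                )
            )
    return patterns


def write_pattern_table(
    patterns: Iterable[PointPattern | BivariatePattern],
    path: str | Path,
    species_labels: tuple[str, str] = ("6nm", "2nm"),
) -> None:
    """Write patterns back to the standard coordinate-table format.

    ``species_labels`` gives the (big, small) labels used for bivariate
    patterns.  Round-trips coordinates at full float precision.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    any_species = False
    for pat in patterns:
        if isinstance(pat, BivariatePattern):
            any_species = True
            parts = [(pat.big, species_labels[0]), (pat.small, species_labels[1])]
        else:
            parts = [(pat, None)]
        for sub, lab in parts:
            w = sub.window
            for x, y in sub.points:
                row = {"image_id": sub.image_id, "x_nm": x, "y_nm": y}
                if lab is not None:
                    row["species"] = lab
                row.update(
                    win_xmin=w.x_min, win_xmax=w.x_max, win_ymin=w.y_min, win_ymax=w.y_max
                )
                rows.append(row)
    cols = ["image_id", "x_nm", "y_nm"]
    if any_species:
        cols.append("species")
    cols += list(_WINDOW_COLS)
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep=sep, index=False, float_format="%.10g"
    )
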
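"""Univariate nanoclustering analysis: K(r), L(r) - r, CSR envelopes, Lmax.

The estimator follows the immunogold EM convention

    K(r) = A n^-2  sum_{i != j} w_ij 1(||x_i - x_j|| <= r)
    L(r) - r = sqrt(K(r) / pi) - r

with A the window area, n the particle count and w_ij an unbiased edge
correction (Ripley's isotropic correction by default, toroidal distances as an
alternative).  L(r) - r is 0 under complete spatial randomness (CSR), positive
for clustering.  The observed curve is standardized pointwise against the
upper percentile (default 99%) of Monte Carlo CSR simulations, so that a
standardized value above 1.0 marks statistically meaningful clustering; the
peak of the standardized curve (Lmax) summarizes clustering strength for one
1 um^2 sheet, and sheets are pooled as mean +/- SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .patterns import (
    DomainError,
    GoldmapError,
    GridMismatchError,
    InsufficientPointsError,
    InsufficientSimulationsError,
    NullEnvelope,
    PointPattern,
    RadialCurve,
    SpatialWindow,
    UndefinedCurveError,
    default_grid,
    isotropic_weights,
    pairwise_distances,
    toroidal_distance_matrix,
)

__all__ = [
    "LmaxSummary",
    "UnivariateStudyResult",
    "k_function",
    "l_minus_r",
    "csr_envelope",
    "standardize",
    "lmax_summary",
    "univariate_study",
]

#: envelope values below this floor (nm) are treated as undefined when dividing
ENVELOPE_FLOOR = 1e-3
#: default lower end of the Lmax search range (nm); below ~10 nm the CSR
#: envelope approaches zero and standardized ratios are unstable
LMAX_SEARCH_MIN = 10.0

_CORRECTIONS = ("isotropic", "toroidal")


def _pair_distances_and_weights(
    points: np.ndarray, window: SpatialWindow, correction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered-pair (i != j) distances and edge weights, flattened."""
    n = points.shape[0]
    if correction == "toroidal":
        dmat = toroidal_distance_matrix(points, points, window)
        off = ~np.eye(n, dtype=bool)
        d = dmat[off]
        return d, np.ones_like(d)
    if correction != "isotropic":
        raise DomainError(f"unknown correction {correction!r}; use one of {_CORRECTIONS}")
    dmat = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    off = ~np.eye(n, dtype=bool)
    d = dmat[off]
    centers = np.repeat(points, n - 1, axis=0)  # row i of dmat[off] keeps center i
    return d, isotropic_weights(centers, d, window)


def _accumulate_k(
    d: np.ndarray, w: np.ndarray, r_grid: np.ndarray, scale: float
) -> np.ndarray:
    """scale * sum of weights over pairs with distance <= r, per grid point."""
    idx = np.searchsorted(r_grid, d, side="left")
    keep = idx < r_grid.size
    counts = np.bincount(idx[keep], weights=w[keep], minlength=r_grid.size)
    return scale * np.cumsum(counts)


def k_function(
    pattern: PointPattern,
    r_grid: np.ndarray | None = None,
    correction: str = "isotropic",
) -> RadialCurve:
    """Univariate Ripley K-function on the distance grid (default 1-240 nm)."""
    if pattern.n < 2:
        raise InsufficientPointsError(
            f"K-function needs n >= 2 points, got n={pattern.n} "
            f"(image {pattern.image_id!r})"
        )
    r_grid = default_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    d, w = _pair_distances_and_weights(pattern.points, pattern.window, correction)
    values = _accumulate_k(d, w, r_grid, pattern.window.area / pattern.n**2)
    return RadialCurve(r_grid, values, kind="K")


def l_minus_r(curve: RadialCurve) -> RadialCurve:
    """Variance-stabilizing transform sqrt(K/pi) - r; 0 under CSR."""
    vals = np.asarray(curve.values, dtype=float)
    if np.any(vals[np.isfinite(vals)] < 0):
        raise DomainError("K values must be >= 0")
    out = np.sqrt(vals / math.pi) - curve.r
    return RadialCurve(curve.r, out, kind="L_minus_r")


def csr_envelope(
    pattern: PointPattern,
    n_sim: int = 1000,
    percentile: float = 99.0,
    seed: int | None = None,
    r_grid: np.ndarray | None = None,
    correction: str = "isotropic",
    rng: np.random.Generator | None = None,
) -> NullEnvelope:
    """Pointwise upper-percentile envelope of L(r) - r under CSR.

    Each simulation redraws the pattern's n points uniformly in its window
    and recomputes L(r) - r with the same edge correction; the envelope is
    the pointwise ``percentile`` quantile (linear interpolation between order
    statistics) across simulations.
    """
    if pattern.n < 2:
        raise InsufficientPointsError("CSR envelope needs n >= 2 points")
    if n_sim < 100:
        raise InsufficientSimulationsError(f"n_sim={n_sim} < 100")
    r_grid = default_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    w = pattern.window
    scale = w.area / pattern.n**2
    sims = np.empty((n_sim, r_grid.size))
    for s in range(n_sim):
        pts = np.column_stack(
            (
                rng.uniform(w.x_min, w.x_max, pattern.n),
                rng.uniform(w.y_min, w.y_max, pattern.n),
            )
        )
        d, wts = _pair_distances_and_weights(pts, w, correction)
        k = _accumulate_k(d, wts, r_grid, scale)
        sims[s] = np.sqrt(k / math.pi) - r_grid
    upper = np.percentile(sims, percentile, axis=0)
    return NullEnvelope(
        r=r_grid,
        upper=upper,
        percentile=float(percentile),
        n_sim=int(n_sim),
        null_model="csr",
        seed=seed,
    )


def standardize(
    curve: RadialCurve, envelope: NullEnvelope, floor: float = ENVELOPE_FLOOR
) -> RadialCurve:
    """Divide a curve pointwise by the envelope's upper percentile.

    A standardized value of 1.0 is the significance boundary at every r.
    Grid points where the envelope is below ``floor`` (small-r instability)
    are flagged undefined (NaN) and excluded from downstream summaries.
    """
    if curve.r.shape != envelope.r.shape or not np.allclose(curve.r, envelope.r):
        raise GridMismatchError("curve and envelope grids differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(envelope.upper >= floor, curve.values / envelope.upper, np.nan)
    return RadialCurve(curve.r, out, kind="standardized")


@dataclass(frozen=True)
class LmaxSummary:
    """Peak of the standardized L(r) - r curve for one sheet."""

    lmax: float
    r_at_lmax: float
    significant: bool
    image_id: str = ""

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "lmax": self.lmax,
            "r_at_lmax_nm": self.r_at_lmax,
            "significant": self.significant,
        }


def lmax_summary(
    standardized: RadialCurve,
    r_min: float = LMAX_SEARCH_MIN,
    r_max: float = 240.0,
    image_id: str = "",
) -> LmaxSummary:
    """Lmax = max standardized value over [r_min, r_max]; ties -> smallest r.

    Clustering is called significant when Lmax strictly exceeds 1.0, the
    standardized 99% confidence boundary.
    """
    in_range = (standardized.r >= r_min) & (standardized.r <= r_max)
    mask = in_range & standardized.defined
    if not mask.any():
        raise UndefinedCurveError(
            f"no defined standardized values in [{r_min}, {r_max}] nm"
        )
    vals = np.where(mask, standardized.values, -np.inf)
    i = int(np.argmax(vals))  # argmax returns the first (smallest-r) maximizer
    lmax = float(standardized.values[i])
    return LmaxSummary(
        lmax=lmax,
        r_at_lmax=float(standardized.r[i]),
        significant=bool(lmax > 1.0),
        image_id=image_id,
    )


@dataclass(frozen=True)
class UnivariateStudyResult:
    """Per-image Lmax summaries pooled as mean +/- SD."""

    summaries: tuple[LmaxSummary, ...]
    mean_lmax: float
    sd_lmax: float
    n_images: int

    @property
    def fraction_significant(self) -> float:
        return sum(s.significant for s in self.summaries) / self.n_images

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "mean_lmax": self.mean_lmax,
            "sd_lmax": self.sd_lmax,
            "fraction_significant": self.fraction_significant,
            "per_image": [s.to_dict() for s in self.summaries],
        }


def univariate_study(
    patterns: list[PointPattern],
    n_sim: int = 1000,
    percentile: float = 99.0,
    seed: int | None = None,
    r_grid: np.ndarray | None = None,
    correction: str = "isotropic",
    r_min: float = LMAX_SEARCH_MIN,
    r_max: float = 240.0,
) -> UnivariateStudyResult:
    """Analyze each sheet independently and pool Lmax as mean +/- SD.

    Every image gets its own CSR envelope matched to its n and window
    (simulation seeds are spawned deterministically from ``seed``).  Errors in
    one image are re-raised annotated with its image_id.
    """
    if not patterns:
        raise DomainError("univariate_study requires at least one pattern")
    child_seeds = np.random.SeedSequence(seed).spawn(len(patterns))
    summaries = []
    for pat, ss in zip(patterns, child_seeds):
        try:
            curve = l_minus_r(k_function(pat, r_grid=r_grid, correction=correction))
            env = csr_envelope(
                pat,
                n_sim=n_sim,
                percentile=percentile,
                r_grid=r_grid,
                correction=correction,
                rng=np.random.default_rng(ss),
            )
            std = standardize(curve, env)
            summaries.append(lmax_summary(std, r_min, r_max, image_id=pat.image_id))
        except GoldmapError as exc:
            raise type(exc)(f"image {pat.image_id!r}: {exc}") from exc
    lmaxes = np.array([s.lmax for s in summaries])
    if len(summaries) == 1:
        warnings.warn("single image: SD of Lmax reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(lmaxes, ddof=1))
    return UnivariateStudyResult(
        summaries=tuple(summaries),
        mean_lmax=float(lmaxes.mean()),
        sd_lmax=sd,
        n_images=len(summaries),
    )
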
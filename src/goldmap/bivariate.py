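"""Two-species coclustering analysis: cross K-functions, L_biv(r) - r, LBI.

For two gold populations ("big" 6 nm, counts n_b; "small" 2 nm, counts n_s)
sharing one window of area A:

    K_bs(r) = A (n_b n_s)^-1 sum_{i in b} sum_{j in s} w_ij 1(d_ij <= r)
    K_sb(r) = the same sum with the roles (and weight centers) swapped
    K_biv(r) = (n_b + n_s)^-1 [ n_b K_sb(r) + n_s K_bs(r) ]
    L_biv(r) - r = sqrt(K_biv(r) / pi) - r

The observed L_biv(r) - r is standardized pointwise against the 95% upper
envelope of a spatial-independence null (random toroidal shifts of the small
population by default, which preserves each species' internal clustering, or
CSR resampling of both).  The standardized curve integrated over 10-110 nm by
the trapezoidal rule is the LBI summary; LBI above 100 (the integral of the
boundary curve that equals 1.0 everywhere) marks significant coclustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .patterns import (
    BivariatePattern,
    DomainError,
    GoldmapError,
    InsufficientPointsError,
    InsufficientSimulationsError,
    NullEnvelope,
    PointPattern,
    RadialCurve,
    SpatialWindow,
    UndefinedCurveError,
    default_grid,
    isotropic_weights,
    toroidal_distance_matrix,
)
from .univariate import ENVELOPE_FLOOR, l_minus_r, standardize

__all__ = [
    "LBI_RANGE",
    "LBISummary",
    "BivariateStudyResult",
    "k_cross",
    "k_bivariate",
    "l_biv_minus_r",
    "independence_envelope",
    "lbi",
    "bivariate_study",
]

#: fixed integration range of the LBI summary, nm
LBI_RANGE = (10.0, 110.0)
#: significance boundary of the LBI summary (integral of the unit curve)
LBI_THRESHOLD = 100.0

_NULL_MODELS = ("toroidal_shift", "csr")


def _cross_k_values(
    big: np.ndarray,
    small: np.ndarray,
    window: SpatialWindow,
    r_grid: np.ndarray,
    correction: str,
    direction: str,
) -> np.ndarray:
    """K_bs ('bs': big distributed around ...; weights centered on big) or K_sb."""
    if direction == "bs":
        centers, others = big, small
    elif direction == "sb":
        centers, others = small, big
    else:
        raise DomainError(f"direction must be 'bs' or 'sb', got {direction!r}")
    if correction == "toroidal":
        d = toroidal_distance_matrix(centers, others, window).ravel()
        w = np.ones_like(d)
    elif correction == "isotropic":
        d = np.linalg.norm(centers[:, None, :] - others[None, :, :], axis=-1).ravel()
        c = np.repeat(centers, others.shape[0], axis=0)
        w = isotropic_weights(c, d, window)
    else:
        raise DomainError(f"unknown correction {correction!r}")
    idx = np.searchsorted(r_grid, d, side="left")
    keep = idx < r_grid.size
    counts = np.bincount(idx[keep], weights=w[keep], minlength=r_grid.size)
    scale = window.area / (big.shape[0] * small.shape[0])
    return scale * np.cumsum(counts)


def k_cross(
    pattern: BivariatePattern,
    direction: str = "bs",
    r_grid: np.ndarray | None = None,
    correction: str = "isotropic",
) -> RadialCurve:
    """Bivariate cross K-function K_bs (big around small) or K_sb."""
    if pattern.n_b < 1 or pattern.n_s < 1:
        raise InsufficientPointsError(
            f"cross K needs both populations non-empty (n_b={pattern.n_b}, "
            f"n_s={pattern.n_s}, image {pattern.image_id!r})"
        )
    r_grid = default_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    vals = _cross_k_values(
        pattern.big.points, pattern.small.points, pattern.window, r_grid,
        correction, direction,
    )
    return RadialCurve(r_grid, vals, kind="K")


def k_bivariate(
    pattern: BivariatePattern,
    r_grid: np.ndarray | None = None,
    correction: str = "isotropic",
) -> RadialCurve:
    """Count-weighted combination of the two cross K-functions."""
    kbs = k_cross(pattern, "bs", r_grid=r_grid, correction=correction)
    ksb = k_cross(pattern, "sb", r_grid=r_grid, correction=correction)
    nb, ns = pattern.n_b, pattern.n_s
    vals = (nb * ksb.values + ns * kbs.values) / (nb + ns)
    return RadialCurve(kbs.r, vals, kind="K_biv")


def l_biv_minus_r(curve: RadialCurve) -> RadialCurve:
    """sqrt(K_biv/pi) - r; 0 reference, negative values toward segregation."""
    out = l_minus_r(curve)
    return RadialCurve(out.r, out.values, kind="L_biv_minus_r")


def _l_biv_values(
    big: np.ndarray,
    small: np.ndarray,
    window: SpatialWindow,
    r_grid: np.ndarray,
    correction: str,
) -> np.ndarray:
    nb, ns = big.shape[0], small.shape[0]
    kbs = _cross_k_values(big, small, window, r_grid, correction, "bs")
    ksb = _cross_k_values(big, small, window, r_grid, correction, "sb")
    kbiv = (nb * ksb + ns * kbs) / (nb + ns)
    return np.sqrt(kbiv / math.pi) - r_grid


def independence_envelope(
    pattern: BivariatePattern,
    n_sim: int = 1000,
    percentile: float = 95.0,
    null_model: str = "toroidal_shift",
    seed: int | None = None,
    r_grid: np.ndarray | None = None,
    correction: str = "isotropic",
    rng: np.random.Generator | None = None,
) -> NullEnvelope:
    """Upper envelope of L_biv(r) - r under a spatial-independence null.

    ``toroidal_shift`` translates the small population by a uniform vector
    with wraparound (big fixed), preserving both marginal structures while
    destroying cross-correlation; ``csr`` redraws both populations uniformly.
    """
    if pattern.n_b < 1 or pattern.n_s < 1:
        raise InsufficientPointsError("independence envelope needs both populations")
    if n_sim < 100:
        raise InsufficientSimulationsError(f"n_sim={n_sim} < 100")
    if null_model not in _NULL_MODELS:
        raise DomainError(f"unknown null_model {null_model!r}; use one of {_NULL_MODELS}")
    r_grid = default_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    w = pattern.window
    big = pattern.big.points
    small = pattern.small.points
    sims = np.empty((n_sim, r_grid.size))
    for s in range(n_sim):
        if null_model == "toroidal_shift":
            shift = rng.uniform([0.0, 0.0], [w.width, w.height])
            moved = small - [w.x_min, w.y_min] + shift
            moved = np.mod(moved, [w.width, w.height]) + [w.x_min, w.y_min]
            b, sm = big, moved
        else:
            b = np.column_stack(
                (rng.uniform(w.x_min, w.x_max, pattern.n_b),
                 rng.uniform(w.y_min, w.y_max, pattern.n_b))
            )
            sm = np.column_stack(
                (rng.uniform(w.x_min, w.x_max, pattern.n_s),
                 rng.uniform(w.y_min, w.y_max, pattern.n_s))
            )
        sims[s] = _l_biv_values(b, sm, w, r_grid, correction)
    upper = np.percentile(sims, percentile, axis=0)
    return NullEnvelope(
        r=r_grid,
        upper=upper,
        percentile=float(percentile),
        n_sim=int(n_sim),
        null_model=null_model,
        seed=seed,
    )


@dataclass(frozen=True)
class LBISummary:
    """Integrated standardized L_biv(r) - r over the fixed 10-110 nm range."""

    lbi: float
    significant: bool
    image_id: str = ""
    r_min: float = LBI_RANGE[0]
    r_max: float = LBI_RANGE[1]
    null_model: str = "toroidal_shift"
    n_sim: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "lbi": self.lbi,
            "significant": self.significant,
            "integration_range_nm": [self.r_min, self.r_max],
            "null_model": self.null_model,
            "n_sim": self.n_sim,
        }


def lbi(
    standardized: RadialCurve,
    r_min: float = LBI_RANGE[0],
    r_max: float = LBI_RANGE[1],
    image_id: str = "",
    null_model: str = "toroidal_shift",
    n_sim: int = 0,
    seed: int | None = None,
) -> LBISummary:
    """Trapezoidal integral of the standardized curve on the 1-nm grid.

    The curve equal to 1.0 everywhere (the 95% boundary) integrates to
    exactly 100 over 10-110 nm; coclustering is called significant above
    that threshold.  Negative standardized values (segregation) integrate
    as-is and lower LBI.  Undefined values inside the range are an error --
    they are never silently interpolated.
    """
    mask = (standardized.r >= r_min) & (standardized.r <= r_max)
    if not mask.any():
        raise UndefinedCurveError(f"grid does not cover [{r_min}, {r_max}] nm")
    vals = standardized.values[mask]
    if not np.all(np.isfinite(vals)):
        bad = standardized.r[mask][~np.isfinite(vals)]
        raise UndefinedCurveError(
            f"standardized curve undefined at r={bad[:3].tolist()} nm inside "
            f"the integration range [{r_min}, {r_max}]"
        )
    value = float(np.trapezoid(vals, standardized.r[mask]))
    return LBISummary(
        lbi=value,
        significant=bool(value > LBI_THRESHOLD),
        image_id=image_id,
        r_min=r_min,
        r_max=r_max,
        null_model=null_model,
        n_sim=n_sim,
        seed=seed,
    )


@dataclass(frozen=True)
class BivariateStudyResult:
    """Per-image LBI summaries pooled as mean +/- SD."""

    summaries: tuple[LBISummary, ...]
    mean_lbi: float
    sd_lbi: float
    n_images: int

    @property
    def fraction_significant(self) -> float:
        return sum(s.significant for s in self.summaries) / self.n_images

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "mean_lbi": self.mean_lbi,
            "sd_lbi": self.sd_lbi,
            "fraction_significant": self.fraction_significant,
            "per_image": [s.to_dict() for s in self.summaries],
        }


def bivariate_study(
    patterns: list[BivariatePattern],
    n_sim: int = 1000,
    percentile: float = 95.0,
    null_model: str = "toroidal_shift",
    seed: int | None = None,
    r_grid: np.ndarray | None = None,
    correction: str = "isotropic",
    r_min: float = LBI_RANGE[0],
    r_max: float = LBI_RANGE[1],
) -> BivariateStudyResult:
    """Analyze each sheet with an image-matched null and pool LBI mean +/- SD."""
    if not patterns:
        raise DomainError("bivariate_study requires at least one pattern")
    child_seeds = np.random.SeedSequence(seed).spawn(len(patterns))
    summaries = []
    for pat, ss in zip(patterns, child_seeds):
        try:
            curve = l_biv_minus_r(k_bivariate(pat, r_grid=r_grid, correction=correction))
            env = independence_envelope(
                pat,
                n_sim=n_sim,
                percentile=percentile,
                null_model=null_model,
                r_grid=r_grid,
                correction=correction,
                rng=np.random.default_rng(ss),
            )
            std = standardize(curve, env, floor=ENVELOPE_FLOOR)
            summaries.append(
                lbi(
                    std,
                    r_min=r_min,
                    r_max=r_max,
                    image_id=pat.image_id,
                    null_model=null_model,
                    n_sim=n_sim,
                    seed=seed,
                )
            )
        except GoldmapError as exc:
            raise type(exc)(f"image {pat.image_id!r}: {exc}") from exc
    vals = np.array([s.lbi for s in summaries])
    if len(summaries) == 1:
        warnings.warn("single image: SD of LBI reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(vals, ddof=1))
    return BivariateStudyResult(
        summaries=tuple(summaries),
        mean_lbi=float(vals.mean()),
        sd_lbi=sd,
        n_images=len(summaries),
    )
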
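"""Seeded generators of synthetic immunogold point patterns.

The generators emulate the statistical structure the spatial analyses assume:
CSR (the univariate null), mixtures of monomers/dimers/higher oligomers with
fixed intra-cluster spacing plus labelling jitter, Thomas parent-offspring
clusters, and two-species patterns that are independent, linked at a fixed
inter-species distance (heterodimer-like) or segregated.  Default window is
the 1 um^2 sheet (1000x1000 nm) and default densities sit near 170
particles/um^2, matching realistic immunogold labelling of membrane sheets.

Every generator is deterministic under a fixed seed, emits exactly the
requested counts inside the window, and returns truth metadata (cluster
membership, linked pairs) for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .patterns import BivariatePattern, DomainError, PointPattern, SpatialWindow

__all__ = [
    "DEFAULT_WINDOW",
    "OligomerMixture",
    "BivariateSimulation",
    "generate_csr",
    "generate_oligomer_mixture",
    "generate_thomas",
    "generate_bivariate",
]

#: the 1 um^2 membrane-sheet window
DEFAULT_WINDOW = SpatialWindow(0.0, 1000.0, 0.0, 1000.0)

_MAX_ANCHOR_RETRIES = 1000


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _uniform_points(rng: np.random.Generator, n: int, window: SpatialWindow) -> np.ndarray:
    return np.column_stack(
        (rng.uniform(window.x_min, window.x_max, n),
         rng.uniform(window.y_min, window.y_max, n))
    )


def generate_csr(
    n: int,
    window: SpatialWindow = DEFAULT_WINDOW,
    seed: int | np.random.Generator | None = None,
    image_id: str = "csr",
) -> PointPattern:
    """n points independent and uniform over the window (CSR)."""
    if n < 0:
        raise DomainError("n must be >= 0")
    rng = _rng(seed)
    return PointPattern(window, _uniform_points(rng, n, window), image_id=image_id)


@dataclass(frozen=True)
class OligomerMixture:
    """A generated mixture pattern with ground-truth cluster membership."""

    pattern: PointPattern
    cluster_ids: np.ndarray  # per-point cluster index
    cluster_sizes: np.ndarray  # per-cluster size, indexed by cluster id

    @property
    def true_fractions(self) -> dict[str, float]:
        """Per-particle monomer/dimer/oligomer fractions of the generator."""
        n = self.pattern.n
        out = {"monomer": 0.0, "dimer": 0.0, "oligomer": 0.0}
        for s in self.cluster_sizes:
            key = "monomer" if s == 1 else "dimer" if s == 2 else "oligomer"
            out[key] += s / n
        return out

    def truth_dict(self) -> dict:
        return {
            "cluster_ids": self.cluster_ids.tolist(),
            "cluster_sizes": self.cluster_sizes.tolist(),
            "true_fractions": self.true_fractions,
        }


def _cluster_offsets(size: int, spacing: float) -> np.ndarray:
    """Member offsets around a cluster anchor: regular polygon of side spacing.

    A dimer is two points `spacing` apart; a k-mer (k >= 3) sits on the
    regular k-gon with side length `spacing`, so every neighbouring pair is
    at the fixed intra-cluster spacing.
    """
    if size == 1:
        return np.zeros((1, 2))
    if size == 2:
        return np.array([[-spacing / 2.0, 0.0], [spacing / 2.0, 0.0]])
    radius = spacing / (2.0 * math.sin(math.pi / size))
    ang = 2.0 * math.pi * np.arange(size) / size
    return radius * np.column_stack((np.cos(ang), np.sin(ang)))


def generate_oligomer_mixture(
    counts: Mapping[int, int],
    spacing: float = 12.0,
    jitter_sd: float = 0.0,
    window: SpatialWindow = DEFAULT_WINDOW,
    seed: int | np.random.Generator | None = None,
    image_id: str = "mixture",
) -> OligomerMixture:
    """Mixture of oligomer classes: ``counts`` maps cluster size -> number.

    Anchors are uniform in the window; members are placed on a randomly
    rotated regular polygon of side ``spacing`` around the anchor, plus
    isotropic Gaussian jitter of SD ``jitter_sd`` (labelling displacement).
    Anchors whose members would fall outside the window are resampled
    (bounded retries), so all points lie inside and counts are exact.
    """
    if spacing <= 0:
        raise DomainError("spacing must be > 0")
    if jitter_sd < 0:
        raise DomainError("jitter_sd must be >= 0")
    if any(s < 1 or c < 0 for s, c in counts.items()):
        raise DomainError("cluster sizes must be >= 1 and counts >= 0")
    rng = _rng(seed)
    pts: list[np.ndarray] = []
    ids: list[int] = []
    sizes: list[int] = []
    cluster = 0
    for size in sorted(counts):
        for _ in range(counts[size]):
            for attempt in range(_MAX_ANCHOR_RETRIES):
                anchor = _uniform_points(rng, 1, window)[0]
                theta = rng.uniform(0.0, 2.0 * math.pi)
                rot = np.array(
                    [[math.cos(theta), -math.sin(theta)],
                     [math.sin(theta), math.cos(theta)]]
                )
                members = anchor + _cluster_offsets(size, spacing) @ rot.T
                if jitter_sd > 0:
                    members = members + rng.normal(0.0, jitter_sd, members.shape)
                if window.contains(members).all():
                    break
            else:
                raise DomainError(
                    f"could not place a size-{size} cluster inside the window "
                    f"after {_MAX_ANCHOR_RETRIES} retries"
                )
            pts.append(members)
            ids.extend([cluster] * size)
            sizes.append(size)
            cluster += 1
    coords = np.vstack(pts) if pts else np.zeros((0, 2))
    return OligomerMixture(
        pattern=PointPattern(window, coords, image_id=image_id),
        cluster_ids=np.asarray(ids, dtype=int),
        cluster_sizes=np.asarray(sizes, dtype=int),
    )


def generate_thomas(
    parent_count: int,
    mean_offspring: float,
    sigma: float,
    window: SpatialWindow = DEFAULT_WINDOW,
    seed: int | np.random.Generator | None = None,
    image_id: str = "thomas",
) -> PointPattern:
    """Thomas cluster process: Poisson offspring around uniform parents.

    Offspring counts are Poisson(``mean_offspring``) per parent and
    displacements isotropic Gaussian(``sigma``); offspring are wrapped
    toroidally into the window so the realized count is kept.
    """
    if parent_count < 0:
        raise DomainError("parent_count must be >= 0")
    if mean_offspring <= 0 or sigma <= 0:
        raise DomainError("mean_offspring and sigma must be > 0")
    rng = _rng(seed)
    parents = _uniform_points(rng, parent_count, window)
    pts = []
    for p in parents:
        k = rng.poisson(mean_offspring)
        if k:
            pts.append(p + rng.normal(0.0, sigma, (k, 2)))
    coords = np.vstack(pts) if pts else np.zeros((0, 2))
    if coords.size:
        origin = np.array([window.x_min, window.y_min])
        dims = np.array([window.width, window.height])
        coords = np.mod(coords - origin, dims) + origin
    return PointPattern(window, coords, image_id=image_id)


@dataclass(frozen=True)
class BivariateSimulation:
    """A generated two-species pattern with linkage ground truth."""

    pattern: BivariatePattern
    mode: str
    link_distance: float | None = None
    linked_pairs: tuple[tuple[int, int], ...] = ()  # (big index, small index)

    def truth_dict(self) -> dict:
        return {
            "mode": self.mode,
            "link_distance_nm": self.link_distance,
            "linked_pairs": [list(p) for p in self.linked_pairs],
        }


def generate_bivariate(
    n_b: int,
    n_s: int,
    mode: str = "independent",
    link_distance: float = 8.0,
    linked_fraction: float = 1.0,
    jitter_sd: float = 0.0,
    window: SpatialWindow = DEFAULT_WINDOW,
    seed: int | np.random.Generator | None = None,
    image_id: str = "bivariate",
) -> BivariateSimulation:
    """Two-species pattern: ``independent``, ``linked`` or ``segregated``.

    independent: both populations CSR.  linked: big CSR; a ``linked_fraction``
    share of the small particles is placed at ``link_distance`` (plus jitter)
    from distinct big partners, the rest CSR — requires enough big partners.
    segregated: species confined to disjoint half-windows.
    """
    if n_b < 0 or n_s < 0:
        raise DomainError("counts must be >= 0")
    if not 0.0 <= linked_fraction <= 1.0:
        raise DomainError("linked_fraction must lie in [0, 1]")
    rng = _rng(seed)

    linked_pairs: list[tuple[int, int]] = []
    if mode == "independent":
        big = _uniform_points(rng, n_b, window)
        small = _uniform_points(rng, n_s, window)
    elif mode == "segregated":
        mid = window.x_min + window.width / 2.0
        left = SpatialWindow(window.x_min, mid, window.y_min, window.y_max)
        right = SpatialWindow(mid, window.x_max, window.y_min, window.y_max)
        big = _uniform_points(rng, n_b, left)
        small = _uniform_points(rng, n_s, right)
    elif mode == "linked":
        if link_distance <= 0:
            raise DomainError("link_distance must be > 0")
        n_linked = int(round(linked_fraction * n_s))
        if n_linked > n_b:
            raise DomainError(
                f"{n_linked} linked small particles need distinct big partners "
                f"but only n_b={n_b} are available"
            )
        big = _uniform_points(rng, n_b, window)
        partners = rng.choice(n_b, size=n_linked, replace=False)
        placed = []
        for j, bi in enumerate(partners):
            for attempt in range(_MAX_ANCHOR_RETRIES):
                theta = rng.uniform(0.0, 2.0 * math.pi)
                pos = big[bi] + link_distance * np.array(
                    [math.cos(theta), math.sin(theta)]
                )
                if jitter_sd > 0:
                    pos = pos + rng.normal(0.0, jitter_sd, 2)
                if window.contains(pos[None, :])[0]:
                    break
            else:
                raise DomainError("could not place a linked partner inside the window")
            placed.append(pos)
            linked_pairs.append((int(bi), j))
        free = _uniform_points(rng, n_s - n_linked, window)
        small = np.vstack([np.asarray(placed).reshape(-1, 2), free])
    else:
        raise DomainError(
            f"unknown mode {mode!r}; use independent, linked or segregated"
        )

    pat = BivariatePattern(
        big=PointPattern(window, big, image_id=image_id),
        small=PointPattern(window, small, image_id=image_id),
    )
    return BivariateSimulation(
        pattern=pat,
        mode=mode,
        link_distance=link_distance if mode == "linked" else None,
        linked_pairs=tuple(linked_pairs),
    )
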
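"""SAINT-scored prey-set computations for proximity maps.

Proximity-MS experiments (BioID, FLAG-MS) score every bait-prey pair with a
SAINT score (SS, a posterior probability in [0, 1]) and a Bayesian FDR.
High-confidence prey sets are obtained by an inclusive SS cut-off (>= 0.7 for
BioID lists, >= 0.9 typical for FLAG-MS); the sets are then compared by
asymmetric overlap percentages, Venn partitions and cross-technique overlaps,
and spectral abundances are expressed as fold change over a control bait.

Prey identity is the identifier string after whitespace trimming and case
normalization; no orthology mapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .patterns import DomainError, PatternTableError

__all__ = [
    "PreyRecord",
    "PreySet",
    "read_prey_table",
    "filter_high_confidence",
    "fold_change_over_control",
    "fold_label",
    "overlap_fraction",
    "venn_partition",
    "technique_overlap",
    "TechniqueOverlap",
]


def _normalize_prey(name: str) -> str:
    return str(name).strip().upper()


@dataclass(frozen=True)
class PreyRecord:
    """One bait-prey observation from a SAINT-scored MS experiment."""

    bait: str
    prey: str
    saint_score: float
    bfdr: float | None = None
    technique: str = "BioID"
    spectral_counts: tuple[int, ...] = ()
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.saint_score <= 1.0:
            raise DomainError(f"SAINT score {self.saint_score} outside [0, 1]")
        if self.bfdr is not None and not 0.0 <= self.bfdr <= 1.0:
            raise DomainError(f"BFDR {self.bfdr} outside [0, 1]")
        if any((c < 0 or int(c) != c) for c in self.spectral_counts):
            raise DomainError("spectral counts must be non-negative integers")


@dataclass(frozen=True)
class PreySet:
    """High-confidence prey identifiers for one bait/technique."""

    bait: str
    members: frozenset[str]
    technique: str = "BioID"
    threshold: float = 0.7

    def __len__(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "bait": self.bait,
            "technique": self.technique,
            "ss_threshold": self.threshold,
            "n": len(self.members),
            "members": sorted(self.members),
        }


def read_prey_table(path: str | Path) -> list[PreyRecord]:
    """Read a delimited prey table (columns bait,prey,ss[,technique,bfdr,...])."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("bait", "prey", "ss"):
        if col not in df.columns:
            raise PatternTableError(f"{path.name}: missing required column {col!r}")
    count_cols = [c for c in df.columns if c.startswith("counts")]
    records = []
    for idx, row in df.iterrows():
        try:
            ss = float(row["ss"])
        except (TypeError, ValueError):
            raise PatternTableError(
                f"{path.name}: malformed SAINT score {row['ss']!r} at file row {idx + 2}"
            ) from None
        records.append(
            PreyRecord(
                bait=str(row["bait"]).strip(),
                prey=str(row["prey"]),
                saint_score=ss,
                bfdr=float(row["bfdr"]) if "bfdr" in df.columns and pd.notna(row.get("bfdr")) else None,
                technique=str(row["technique"]).strip() if "technique" in df.columns else "BioID",
                spectral_counts=tuple(int(row[c]) for c in count_cols if pd.notna(row[c])),
                fold_change=float(row["fold_change"])
                if "fold_change" in df.columns and pd.notna(row.get("fold_change"))
                else None,
            )
        )
    return records


def filter_high_confidence(
    records: Iterable[PreyRecord],
    bait: str,
    ss_threshold: float = 0.7,
    technique: str | None = None,
) -> PreySet:
    """Unique prey for one bait with SS >= threshold (inclusive boundary)."""
    if not 0.0 <= ss_threshold <= 1.0:
        raise DomainError(f"ss_threshold {ss_threshold} outside [0, 1]")
    records = list(records)
    seen_bait = False
    members = set()
    techniques = set()
    for rec in records:
        if rec.bait != bait:
            continue
        if technique is not None and rec.technique != technique:
            continue
        seen_bait = True
        techniques.add(rec.technique)
        if rec.saint_score >= ss_threshold:
            members.add(_normalize_prey(rec.prey))
    if not seen_bait:
        warnings.warn(f"no records for bait {bait!r}; returning empty set", stacklevel=2)
    return PreySet(
        bait=bait,
        members=frozenset(members),
        technique=technique or ("/".join(sorted(techniques)) if techniques else "unknown"),
        threshold=float(ss_threshold),
    )


def fold_change_over_control(value: float, control_value: float) -> float:
    """Ratio of a measured quantity over its control (e.g. GFP) value."""
    if control_value <= 0:
        raise DomainError(f"control value must be > 0, got {control_value}")
    return float(value) / float(control_value)


def fold_label(ratio: float) -> str:
    """Human-readable 'n-fold' form, rounded to the nearest integer."""
    return f"{round(ratio)}-fold"


def overlap_fraction(a: PreySet, b: PreySet) -> float:
    """Percentage of a's members also found in b (asymmetric)."""
    if not a.members:
        raise DomainError(f"overlap fraction undefined for empty set ({a.bait})")
    return 100.0 * len(a.members & b.members) / len(a.members)


def venn_partition(sets: Sequence[PreySet]) -> dict[str, int]:
    """Counts of every exclusive Venn region for 2 or 3 prey sets.

    Region keys join the bait labels of the sets a member belongs to with
    '&' (e.g. ``AC5``, ``AC5&AC6``, ``AC5&AC6&AC9``); regions are disjoint
    and sum to the size of the union.
    """
    if len(sets) not in (2, 3):
        raise DomainError("venn_partition takes 2 or 3 sets")
    names = [s.bait for s in sets]
    if len(set(names)) != len(names):
        raise DomainError("sets must carry distinct bait labels")
    regions: dict[str, int] = {}
    for include in product([True, False], repeat=len(sets)):
        if not any(include):
            continue
        key = "&".join(n for n, inc in zip(names, include) if inc)
        region = frozenset.intersection(
            *(s.members for s, inc in zip(sets, include) if inc)
        )
        for s, inc in zip(sets, include):
            if not inc:
                region = region - s.members
        regions[key] = len(region)
    return regions


@dataclass(frozen=True)
class TechniqueOverlap:
    """Shared prey between two techniques for one bait."""

    shared: frozenset[str]
    n_a: int
    n_b: int

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def fraction_a(self) -> float:
        """Percent of the first set that is shared."""
        return 100.0 * self.n_shared / self.n_a if self.n_a else 0.0

    @property
    def fraction_b(self) -> float:
        return 100.0 * self.n_shared / self.n_b if self.n_b else 0.0

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "shared": sorted(self.shared),
            "fraction_of_first_pct": self.fraction_a,
            "fraction_of_second_pct": self.fraction_b,
        }


def technique_overlap(a: PreySet, b: PreySet) -> TechniqueOverlap:
    """Intersection of two prey sets with per-set shared percentages."""
    shared = a.members & b.members
    return TechniqueOverlap(shared=frozenset(shared), n_a=len(a), n_b=len(b))
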
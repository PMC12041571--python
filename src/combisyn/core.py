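"""Core domain types for combination synergy screens.

A screen measures pairwise drug combinations on a dose-response matrix and
summarises each pair with a gamma synergy score: gamma < 0.95 is called
synergistic, gamma < 0.5 strongly synergistic.  Pairs are unordered, so a
single canonical key type is shared by every downstream stage.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Gamma threshold below which a combination is called synergistic.  The
#: boundary itself (gamma == 0.95) is non-synergistic.
GAMMA_SYNERGY_CUTOFF = 0.95

#: Gamma threshold for "strong" synergy.
GAMMA_STRONG_CUTOFF = 0.5


class SelfPairError(ValueError):
    """A compound cannot be combined with itself."""


_KeyBase = namedtuple("_KeyBase", ["first", "second"])


class CombinationKey(_KeyBase):
    """Canonical unordered compound pair (``first < second`` lexicographically)."""

    __slots__ = ()

    def __new__(cls, first: str, second: str):
        if first == second:
            raise SelfPairError(f"self-pair {first!r} is not a combination")
        a, b = sorted((str(first), str(second)))
        return super().__new__(cls, a, b)


def make_key(a: str, b: str) -> CombinationKey:
    """Build the canonical key for the unordered pair ``{a, b}``.

    Raises :class:`SelfPairError` when ``a == b``.
    """
    return CombinationKey(a, b)


@dataclass(frozen=True)
class Compound:
    """One screened molecule.

    ``log_ic50`` is log10 molar potency (e.g. -7.0 = 100 nM) and must be
    finite for active compounds; inactive compounds may carry NaN.
    """

    id: str
    smiles: str
    log_ic50: float = math.nan
    moa_labels: frozenset = field(default_factory=frozenset)
    is_active: bool = False
    in_training: bool = False

    def __post_init__(self):
        object.__setattr__(self, "moa_labels", frozenset(self.moa_labels))
        if self.is_active and not math.isfinite(self.log_ic50):
            raise ValueError(f"active compound {self.id!r} requires a finite log_ic50")

    @property
    def primary_moa(self) -> str | None:
        """First MoA label in sorted order, or None if unannotated."""
        return min(self.moa_labels) if self.moa_labels else None


def label_synergy(gamma_mean: float) -> bool:
    """True iff ``gamma_mean`` < 0.95 (the boundary counts as non-synergistic)."""
    if not math.isfinite(gamma_mean):
        raise ValueError(f"gamma must be finite, got {gamma_mean!r}")
    return gamma_mean < GAMMA_SYNERGY_CUTOFF


def is_strong_synergy(gamma_mean: float) -> bool:
    """True iff ``gamma_mean`` < 0.5."""
    if not math.isfinite(gamma_mean):
        raise ValueError(f"gamma must be finite, got {gamma_mean!r}")
    return gamma_mean < GAMMA_STRONG_CUTOFF


@dataclass(frozen=True)
class SynergyRecord:
    """Per-pair synergy measurement: replicate gammas, their mean, and the label."""

    key: CombinationKey
    gamma_replicates: tuple
    gamma_mean: float
    label: bool

    def __post_init__(self):
        object.__setattr__(self, "gamma_replicates", tuple(float(g) for g in self.gamma_replicates))
        expected = sum(self.gamma_replicates) / len(self.gamma_replicates)
        if not math.isclose(self.gamma_mean, expected, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"gamma_mean {self.gamma_mean} does not match replicate mean {expected}"
            )
        if self.label != label_synergy(self.gamma_mean):
            raise ValueError("label inconsistent with gamma_mean < 0.95 rule")

    @classmethod
    def from_replicates(cls, key: CombinationKey, gammas: Sequence[float]) -> "SynergyRecord":
        gammas = tuple(float(g) for g in gammas)
        mean = sum(gammas) / len(gammas)
        return cls(key=key, gamma_replicates=gammas, gamma_mean=mean, label=label_synergy(mean))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def moa_pair(a: str, b: str) -> tuple:
    """Canonical unordered MoA-label pair (self-pairs allowed)."""
    return (a, b) if a <= b else (b, a)


def _ids(library: Iterable) -> list:
    ids = [c.id if isinstance(c, Compound) else str(c) for c in library]
    if len(set(ids)) != len(ids):
        raise ValueError("library ids must be unique")
    return ids


def enumerate_pairs(library: Iterable, exclude: Iterable = ()) -> list:
    """All C(n,2) unordered pairs over ``library`` minus ``exclude``, sorted.

    ``library`` may contain :class:`Compound` objects or bare id strings.
    """
    ids = sorted(_ids(library))
    excluded = frozenset(exclude)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            key = CombinationKey(a, b)
            if key not in excluded:
                out.append(key)
    return out
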
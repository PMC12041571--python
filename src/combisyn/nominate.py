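"""Turning scored candidate pools into ranked top-30 nomination lists.

Three strategies mirror the teams in the study design: a plain top-k by
score, a three-tier filter/rank scheme driven by activity, training
membership and synergistic MoA pairs, and a top-k with a per-compound
diversity cap.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .core import moa_pair
from .models import PredictionSet


@dataclass(frozen=True)
class NominationEntry:
    rank: int
    key: object
    score: float
    tier_label: str = ""


@dataclass(frozen=True)
class NominationList:
    entries: tuple
    team: str
    name: str = ""

    def __post_init__(self):
        ranks = [e.rank for e in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be contiguous starting at 1")
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("nominated keys must be unique")

    @property
    def keys(self) -> list:
        return [e.key for e in self.entries]


@dataclass(frozen=True)
class MoAPairTable:
    """Per-MoA-pair training statistics and the selected synergistic subset."""

    pairs: dict  # moa pair -> (count, mean label)
    selected: frozenset


def synergistic_moa_pairs(records, moa_map: dict, min_count: int = 3, min_mean: float = 0.66) -> MoAPairTable:
    """Aggregate training labels per unordered MoA pair and select synergistic ones.

    ``moa_map`` gives one (primary) MoA label per compound id; each record
    contributes one row keyed by the sorted pair of its compounds' labels.
    Pairs with at least ``min_count`` drug pairs and mean label >=
    ``min_mean`` are selected.
    """
    counts: Counter = Counter()
    positives: Counter = Counter()
    for r in records:
        for cid in (r.key.first, r.key.second):
            if cid not in moa_map:
                raise KeyError(f"compound {cid!r} missing from MoA map")
        pair = moa_pair(moa_map[r.key.first], moa_map[r.key.second])
        counts[pair] += 1
        positives[pair] += int(r.label)
    pairs = {p: (counts[p], positives[p] / counts[p]) for p in counts}
    selected = frozenset(p for p, (n, mean) in pairs.items() if n >= min_count and mean >= min_mean)
    return MoAPairTable(pairs=pairs, selected=selected)


def _sorted_candidates(scores: dict):
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def topk_nomination(scores: PredictionSet, k: int = 30, name: str = "") -> NominationList:
    """The k highest-scoring pairs; ties broken by canonical key order."""
    if len(scores.scores) < k:
        raise ValueError(f"need at least {k} scored pairs, have {len(scores.scores)}")
    entries = tuple(
        NominationEntry(rank=i + 1, key=key, score=s)
        for i, (key, s) in enumerate(_sorted_candidates(scores.scores)[:k])
    )
    return NominationList(entries=entries, team="topk", name=name or scores.model_id)


@dataclass(frozen=True)
class TierParams:
    tier1_quota: int = 12
    tier2_quota: int = 12
    tier3_quota: int = 6
    consensus_cutoff: float = 0.7


def tiered_nomination(
    consensus: PredictionSet,
    descriptor_only: PredictionSet,
    compounds,
    moa_table: MoAPairTable,
    moa_map: dict | None = None,
    params: TierParams = TierParams(),
    name: str = "tiered",
) -> NominationList:
    """Three mutually exclusive nomination tiers.

    Tier 1 (ranks 1-12): consensus score above the cutoff, both compounds
    active, exactly one in training, MoA pair selected.  Tier 2 (13-24):
    highest descriptor-only scores with both active, one in training, MoA
    pair NOT selected.  Tier 3 (25-30): highest consensus scores with both
    active, none in training, MoA pair selected.  Shortfalls shrink the
    list (with a warning); tiers are never backfilled from one another.
    """
    by_id = {c.id: c for c in compounds}
    if moa_map is None:
        moa_map = {c.id: c.primary_moa for c in compounds}
    pool = set(consensus.scores)
    if not pool <= set(descriptor_only.scores):
        raise ValueError("descriptor-only scores must cover the candidate pool")

    def traits(key):
        a, b = by_id[key.first], by_id[key.second]
        both_active = a.is_active and b.is_active
        n_train = int(a.in_training) + int(b.in_training)
        selected = moa_pair(moa_map[key.first], moa_map[key.second]) in moa_table.selected
        return both_active, n_train, selected

    tier_defs = [
        ("tier1", params.tier1_quota, consensus,
         lambda t, key: t[0] and t[1] == 1 and t[2] and consensus.scores[key] > params.consensus_cutoff),
        ("tier2", params.tier2_quota, descriptor_only,
         lambda t, key: t[0] and t[1] == 1 and not t[2]),
        ("tier3", params.tier3_quota, consensus,
         lambda t, key: t[0] and t[1] == 0 and t[2]),
    ]
    entries = []
    taken = set()
    rank = 1
    for label, quota, ranking, accept in tier_defs:
        members = [
            (key, s)
            for key, s in _sorted_candidates(ranking.scores)
            if key in pool and key not in taken and accept(traits(key), key)
        ][:quota]
        if len(members) < quota:
            warnings.warn(f"{label} filled {len(members)} of {quota} slots")
        for key, s in members:
            entries.append(NominationEntry(rank=rank, key=key, score=s, tier_label=label))
            taken.add(key)
            rank += 1
    return NominationList(entries=tuple(entries), team="tiered", name=name)


def diversity_capped_topk(
    scores: PredictionSet, k: int = 30, per_compound_cap: int = 5, name: str = ""
) -> NominationList:
    """Greedy top-k skipping pairs that would exceed the per-compound cap."""
    usage: Counter = Counter()
    entries = []
    for key, s in _sorted_candidates(scores.scores):
        if len(entries) == k:
            break
        if usage[key.first] >= per_compound_cap or usage[key.second] >= per_compound_cap:
            continue
        usage[key.first] += 1
        usage[key.second] += 1
        entries.append(NominationEntry(rank=len(entries) + 1, key=key, score=s))
    if len(entries) < k:
        warnings.warn(f"diversity cap allows only {len(entries)} of {k} requested nominations")
    return NominationList(entries=tuple(entries), team="diversity_capped", name=name or scores.model_id)


def overlap_report(lists) -> dict:
    """Pairwise shared-key counts and the union size across nomination lists."""
    if len(lists) < 2:
        raise ValueError("need at least two nomination lists")
    names = [nl.name or nl.team for nl in lists]
    out = {}
    union = set()
    for i, a in enumerate(lists):
        union |= set(a.keys)
        for j in range(i + 1, len(lists)):
            out[(names[i], names[j])] = len(set(a.keys) & set(lists[j].keys))
    out["union"] = len(union)
    return out
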
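"""MoA co-occurrence network over synergistic combinations, with a
permutation significance test.

Each synergistic combination contributes its cross-compound MoA label
pairs as edges; recurring edges suggest mechanism-level synergy.  Whether
an edge's frequency exceeds chance is tested against a null built by
resampling the same number of random combinations from the same compound
pool.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .core import CombinationKey, moa_pair


@dataclass(frozen=True)
class MoANetwork:
    """Node and edge frequencies among synergistic combinations."""

    nodes: dict  # MoA label -> frequency
    edges: dict  # unordered MoA pair -> frequency
    edge_mean_gamma: dict  # unordered MoA pair -> mean gamma of contributors
    gamma_cutoff: float


def _labels(value) -> set:
    """Accept a single MoA label or any iterable of labels."""
    return {value} if isinstance(value, str) else set(value)


def _edge_multiset(labels_a, labels_b, primary_only: bool = False):
    """Cross-compound MoA pairs contributed by one combination.

    Counts the full label cross-product (a record with |moa(A)| * |moa(B)|
    label pairs contributes that many edge increments); ``primary_only``
    restricts each compound to its first label.
    """
    la = [min(labels_a)] if primary_only and labels_a else sorted(labels_a)
    lb = [min(labels_b)] if primary_only and labels_b else sorted(labels_b)
    return [moa_pair(x, y) for x in la for y in lb]


def build_network(records, moa_map: dict, gamma_cutoff: float = 0.95, primary_only: bool = False) -> MoANetwork:
    """Co-occurrence network over records with gamma_mean below the cutoff."""
    nodes: Counter = Counter()
    edges: Counter = Counter()
    gamma_sums: Counter = Counter()
    for r in records:
        for cid in (r.key.first, r.key.second):
            if cid not in moa_map:
                raise KeyError(f"compound {cid!r} missing from MoA map")
        if r.gamma_mean >= gamma_cutoff:
            continue
        la, lb = _labels(moa_map[r.key.first]), _labels(moa_map[r.key.second])
        for label in la | lb:
            nodes[label] += 1
        for edge in _edge_multiset(la, lb, primary_only):
            edges[edge] += 1
            gamma_sums[edge] += r.gamma_mean
    edge_mean_gamma = {e: gamma_sums[e] / edges[e] for e in edges}
    return MoANetwork(nodes=dict(nodes), edges=dict(edges), edge_mean_gamma=edge_mean_gamma, gamma_cutoff=gamma_cutoff)


@dataclass(frozen=True)
class PermutationNull:
    n_reps: int
    n_combos_per_rep: int
    per_pair_counts: dict  # MoA pair -> np.ndarray of length n_reps
    seed: int


def permutation_null(
    compound_pool,
    moa_map: dict,
    n_combos: int,
    n_reps: int = 1000,
    seed: int = 0,
    primary_only: bool = False,
) -> PermutationNull:
    """Null edge-frequency distributions from random combination draws.

    Each replicate samples ``n_combos`` distinct unordered pairs uniformly
    from the pool (without replacement within the replicate) and counts MoA
    pair occurrences with the same cross-product rule as
    :func:`build_network`.
    """
    ids = sorted(c.id if hasattr(c, "id") else str(c) for c in compound_pool)
    if len(ids) < 2:
        raise ValueError("pool must contain at least two compounds")
    all_pairs = list(combinations(ids, 2))
    if n_combos > len(all_pairs):
        raise ValueError(f"cannot draw {n_combos} distinct pairs from {len(all_pairs)} possible")
    # Precompute each candidate pair's edge contributions once.
    contribs = [
        _edge_multiset(_labels(moa_map[a]), _labels(moa_map[b]), primary_only) for a, b in all_pairs
    ]
    rng = np.random.default_rng(seed)
    counts: dict = {}
    for rep in range(n_reps):
        chosen = rng.choice(len(all_pairs), size=n_combos, replace=False)
        rep_counts: Counter = Counter()
        for i in chosen:
            rep_counts.update(contribs[i])
        for edge, n in rep_counts.items():
            counts.setdefault(edge, np.zeros(n_reps, dtype=int))[rep] = n
    return PermutationNull(n_reps=n_reps, n_combos_per_rep=n_combos, per_pair_counts=counts, seed=seed)


@dataclass(frozen=True)
class SignificanceResult:
    observed: int
    p_value: float        # add-one empirical estimate, in (0, 1]
    p_normal: float       # one-sided normal approximation from the null mean/sd
    null_mean: float
    null_sd: float
    n_reps: int


def empirical_significance(observed: int, null_counts) -> SignificanceResult:
    """Right-tail significance of an observed edge count against its null.

    Two estimates are returned: the add-one permutation p-value
    ``(1 + #{null >= observed}) / (1 + n_reps)``, which is bounded below
    by 1/(n_reps + 1), and a one-sided normal approximation from the
    null's mean and standard deviation (the estimate matching a reported
    mean +/- standard error summary).
    """
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValueError("null distribution is empty")
    n = null_counts.size
    p_emp = (1 + int((null_counts >= observed).sum())) / (1 + n)
    mean = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1)) if n > 1 else math.nan
    p_norm = float(norm.sf((observed - mean) / sd)) if sd and sd > 0 else math.nan
    return SignificanceResult(
        observed=int(observed), p_value=p_emp, p_normal=p_norm, null_mean=mean, null_sd=sd, n_reps=n
    )
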
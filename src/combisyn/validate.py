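"""Combination-aware cross-validation, randomization controls, and metrics.

Splitting drug pairs at random leaks compounds between training and
validation; the schemes here respect compound identity.  One-compound-out
withholds every pair containing one designated compound (the standard
scheme for this screen: 32 compounds -> 32 folds); everything-out is
stricter, validating only pairs whose compounds are both unseen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import Compound, ConfusionCounts, SynergyRecord


@dataclass(frozen=True)
class FoldSpec:
    fold_id: int
    held_out_compounds: frozenset
    train_keys: tuple
    validation_keys: tuple


def _round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.005 -> 0.01), as in reported tables."""
    if not math.isfinite(x):
        return x
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class MetricReport:
    """Classification metrics; ratios with zero denominators are NaN, never 0."""

    counts: ConfusionCounts
    sens: float
    spec: float
    ppv: float
    npv: float
    bacc: float
    auc: float = math.nan
    hit_rate: float = math.nan

    @property
    def ccr(self) -> float:
        """Correct classification rate, reported as balanced accuracy."""
        return self.bacc

    def rounded(self, ndigits: int = 2) -> dict:
        """Table-style values rounded half away from zero."""
        return {
            name: _round_half_away(getattr(self, name), ndigits)
            for name in ("sens", "spec", "ppv", "npv", "bacc", "auc", "hit_rate")
        }


def one_compound_out_folds(compounds, records) -> list:
    """One fold per compound: validation = every pair containing it.

    Each pair has two members, so each record lands in exactly two folds'
    validation sets.
    """
    ids = sorted(c.id if isinstance(c, Compound) else str(c) for c in compounds)
    known = set(ids)
    for r in records:
        if r.key.first not in known or r.key.second not in known:
            raise ValueError(f"record {r.key} references compounds outside the list")
    folds = []
    for fold_id, cid in enumerate(ids):
        val = tuple(r.key for r in records if cid in r.key)
        train = tuple(r.key for r in records if cid not in r.key)
        folds.append(
            FoldSpec(fold_id=fold_id, held_out_compounds=frozenset([cid]), train_keys=train, validation_keys=val)
        )
    return folds


def everything_out_folds(compounds, records, n_groups: int = 2, seed: int = 0) -> list:
    """Group-out folds: validation pairs share no compound with training pairs.

    Compounds are partitioned at random into ``n_groups``; fold g validates
    pairs fully inside group g and trains on pairs fully outside it; pairs
    straddling the boundary are dropped from that fold.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    ids = sorted(c.id if isinstance(c, Compound) else str(c) for c in compounds)
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    groups = [set(g) for g in np.array_split(np.array(order), n_groups)]
    folds = []
    for fold_id, group in enumerate(groups):
        val = tuple(r.key for r in records if r.key.first in group and r.key.second in group)
        train = tuple(r.key for r in records if r.key.first not in group and r.key.second not in group)
        if not val:
            warnings.warn(f"everything-out fold {fold_id} has an empty validation set")
        folds.append(
            FoldSpec(fold_id=fold_id, held_out_compounds=frozenset(group), train_keys=train, validation_keys=val)
        )
    return folds


def y_randomize(records, seed: int = 0) -> list:
    """Permute the response (replicates, mean, label) across keys.

    The multiset of labels is preserved; any model rebuilt on the result
    should perform at chance.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to permute")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    return [
        SynergyRecord(
            key=records[i].key,
            gamma_replicates=records[j].gamma_replicates,
            gamma_mean=records[j].gamma_mean,
            label=records[j].label,
        )
        for i, j in enumerate(perm)
    ]


def confusion_metrics(c: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity, PPV, NPV and balanced accuracy from counts."""
    if c.total == 0:
        raise ValueError("confusion counts are empty")

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    bacc = (sens + spec) / 2 if math.isfinite(sens) and math.isfinite(spec) else math.nan
    return MetricReport(
        counts=c,
        sens=sens,
        spec=spec,
        ppv=ratio(c.tp, c.tp + c.fp),
        npv=ratio(c.tn, c.tn + c.fn),
        bacc=bacc,
    )


def confusion_from_scores(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold scores (>= threshold = positive call) against boolean labels."""
    tp = tn = fp = fn = 0
    for s, y in zip(scores, labels, strict=True):
        call = s >= threshold
        if call and y:
            tp += 1
        elif call and not y:
            fp += 1
        elif not call and y:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with ties averaged.

    Returns NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def hit_rate(nominated, truth: dict) -> float:
    """Fraction of nominated pairs whose truth label is synergistic."""
    if not nominated:
        raise ValueError("no nominations given")
    missing = [k for k in nominated if k not in truth]
    if missing:
        raise KeyError(f"nominated pairs missing from truth: {missing[:5]}")
    hits = sum(1 for k in nominated if truth[k])
    return hits / len(nominated)


def hit_rate_percent(nominated, truth: dict) -> int:
    """Hit rate as a rounded integer percent (half away from zero)."""
    return int(_round_half_away(100 * hit_rate(nominated, truth), 0))
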
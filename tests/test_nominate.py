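"""MoA-pair selection and the three nomination strategies."""

import dataclasses

import numpy as np
import pytest

import combisyn as cs
from combisyn import PredictionSet, TierParams


def _records(entries):
    """entries: (id_a, id_b, label) -> SynergyRecord list with gamma 0.5/1.2."""
    return [
        cs.SynergyRecord.from_replicates(cs.make_key(a, b), (0.5, 0.5) if lab else (1.2, 1.2))
        for a, b, lab in entries
    ]


class TestSynergisticMoaPairs:
    moa = {"a1": "P", "a2": "P", "a3": "P", "h1": "H", "h2": "H", "x1": "X"}

    def test_threshold_arithmetic(self):
        records = _records([("a1", "h1", 1), ("a2", "h1", 1), ("a3", "h2", 0)])
        table = cs.synergistic_moa_pairs(records, self.moa)
        assert table.pairs[("H", "P")] == (3, pytest.approx(2 / 3))
        assert ("H", "P") in table.selected  # 0.667 >= 0.66

    def test_count_below_minimum_not_selected(self):
        records = _records([("a1", "h1", 1), ("a2", "h2", 1)])
        table = cs.synergistic_moa_pairs(records, self.moa)
        assert ("H", "P") not in table.selected

    def test_truth_pair_selected_on_noiseless_screen(self, small_screen):
        truth = dataclasses.replace(small_screen["truth"], replicate_noise_sd=0, compound_noise_sd=0)
        records, _ = cs.simulate_screen(small_screen["training"], truth, with_matrices=False)
        primary = {c.id: c.primary_moa for c in small_screen["training"]}
        table = cs.synergistic_moa_pairs(records, primary)
        assert cs.moa_pair("proteasome inhibitor", "HDAC inhibitor") in table.selected


def _scored_pool(n_compounds=20, seed=0, prefix="c"):
    rng = np.random.default_rng(seed)
    keys = cs.enumerate_pairs([f"{prefix}{i:03d}" for i in range(n_compounds)])
    return PredictionSet("s", dict(zip(keys, rng.random(len(keys)))))


class TestTopkNomination:
    def test_scores_non_increasing(self):
        nl = cs.topk_nomination(_scored_pool(), k=30)
        scores = [e.score for e in nl.entries]
        assert scores == sorted(scores, reverse=True)
        assert [e.rank for e in nl.entries] == list(range(1, 31))

    def test_tie_broken_by_key_order(self):
        keys = cs.enumerate_pairs(["a", "b", "c", "d"])
        ps = PredictionSet("s", dict.fromkeys(keys, 0.5))
        nl = cs.topk_nomination(ps, k=3)
        assert nl.keys == sorted(keys)[:3]

    def test_k_larger_than_pool_rejected(self):
        with pytest.raises(ValueError):
            cs.topk_nomination(_scored_pool(5), k=30)


def engineered_pool():
    """Candidate pool guaranteed to fill tiers at 12/12/6.

    Compounds: t* are active training compounds, n* active non-training,
    i* inactive.  MoA P-H is the selected synergistic pair; MoA X-Y is not.
    """
    compounds, moa = [], {}

    def add(cid, active, training, label):
        compounds.append(
            cs.Compound(
                id=cid, smiles="CCO", log_ic50=-7.0 if active else float("nan"),
                moa_labels={label}, is_active=active, in_training=training,
            )
        )
        moa[cid] = label

    for i in range(12):
        add(f"t{i:02d}", True, True, "P" if i % 2 else "X")
    for i in range(26):
        add(f"n{i:02d}", True, False, ["H", "Y", "P"][i % 3])
    add("i00", False, False, "H")

    # Selected MoA table: (H, P) synergistic; nothing else.
    table = cs.MoAPairTable(pairs={("H", "P"): (5, 0.8)}, selected=frozenset({("H", "P")}))

    rng = np.random.default_rng(1)
    keys = cs.enumerate_pairs(compounds)
    consensus = PredictionSet("consensus", {k: float(rng.uniform(0.71, 0.99)) for k in keys})
    descriptor = PredictionSet("descriptor", {k: float(rng.random()) for k in keys})
    return compounds, moa, table, consensus, descriptor


class TestTieredNomination:
    def test_full_quota_tiers(self):
        compounds, moa, table, consensus, descriptor = engineered_pool()
        nl = cs.tiered_nomination(consensus, descriptor, compounds, table, moa_map=moa)
        tiers = [e.tier_label for e in nl.entries]
        assert len(nl.entries) == 30
        assert tiers.count("tier1") == 12 and tiers.count("tier2") == 12 and tiers.count("tier3") == 6
        assert [e.rank for e in nl.entries] == list(range(1, 31))

    def test_tier_filters_hold(self):
        compounds, moa, table, consensus, descriptor = engineered_pool()
        by_id = {c.id: c for c in compounds}
        nl = cs.tiered_nomination(consensus, descriptor, compounds, table, moa_map=moa)
        for e in nl.entries:
            a, b = by_id[e.key.first], by_id[e.key.second]
            n_train = a.in_training + b.in_training
            selected = cs.moa_pair(moa[a.id], moa[b.id]) in table.selected
            assert a.is_active and b.is_active
            if e.tier_label == "tier1":
                assert n_train == 1 and selected and consensus.scores[e.key] > 0.7
            elif e.tier_label == "tier2":
                assert n_train == 1 and not selected
            else:
                assert n_train == 0 and selected

    def test_tiers_mutually_exclusive(self):
        compounds, moa, table, consensus, descriptor = engineered_pool()
        nl = cs.tiered_nomination(consensus, descriptor, compounds, table, moa_map=moa)
        assert len(set(nl.keys)) == len(nl.keys)

    def test_empty_moa_table_empties_tiers_1_and_3(self):
        compounds, moa, _, consensus, descriptor = engineered_pool()
        empty = cs.MoAPairTable(pairs={}, selected=frozenset())
        with pytest.warns(UserWarning):
            nl = cs.tiered_nomination(consensus, descriptor, compounds, empty, moa_map=moa)
        tiers = [e.tier_label for e in nl.entries]
        assert tiers.count("tier1") == 0 and tiers.count("tier3") == 0
        assert tiers.count("tier2") == 12


class TestDiversityCappedTopk:
    def test_dominant_compound_capped_at_five(self):
        keys = [cs.make_key("hub", f"p{i:02d}") for i in range(40)]
        keys += cs.enumerate_pairs([f"q{i:02d}" for i in range(12)])
        rng = np.random.default_rng(0)
        scores = {k: (1.0 - 0.001 * i if "hub" in k else 0.5 * rng.random()) for i, k in enumerate(keys)}
        nl = cs.diversity_capped_topk(PredictionSet("s", scores), k=30, per_compound_cap=5)
        assert sum(1 for k in nl.keys if "hub" in k) == 5

    def test_infinite_cap_reduces_to_topk(self):
        ps = _scored_pool(seed=3)
        plain = cs.topk_nomination(ps, k=30)
        capped = cs.diversity_capped_topk(ps, k=30, per_compound_cap=10**9)
        assert plain.keys == capped.keys

    @pytest.mark.parametrize("seed", range(20))
    def test_cap_never_exceeded_random_scores(self, seed):
        from collections import Counter

        ps = _scored_pool(n_compounds=46, seed=seed)  # 1035 candidate pairs
        nl = cs.diversity_capped_topk(ps, k=30, per_compound_cap=5)
        usage = Counter(c for k in nl.keys for c in k)
        assert len(nl.entries) == 30
        assert max(usage.values()) <= 5


class TestOverlapReport:
    def _list_of(self, ids, name):
        keys = cs.enumerate_pairs(ids)[:30]
        entries = tuple(
            cs.nominate.NominationEntry(rank=i + 1, key=k, score=1.0 - i * 0.01)
            for i, k in enumerate(keys)
        )
        return cs.NominationList(entries=entries, team="topk", name=name)

    def test_disjoint_and_shared_unions(self):
        a = self._list_of([f"a{i}" for i in range(9)], "A")
        b = self._list_of([f"b{i}" for i in range(9)], "B")
        c = self._list_of([f"c{i}" for i in range(9)], "C")
        report = cs.overlap_report([a, b, c])
        assert report["union"] == 90
        assert report[("A", "B")] == 0
        report2 = cs.overlap_report([a, a])
        assert report2["union"] == 30 and report2[("A", "A")] == 30
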
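"""Cross-validation splitters, Y-randomization, and performance metrics."""

import itertools
import math

import numpy as np
import pytest

import combisyn as cs
from combisyn import ConfusionCounts, confusion_metrics, hit_rate, hit_rate_percent, roc_auc


class TestOneCompoundOutFolds:
    def test_structure_on_full_screen(self, full_screen):
        folds = cs.one_compound_out_folds(full_screen["training"], full_screen["records"])
        assert len(folds) == 32
        for fold in folds:
            assert len(fold.validation_keys) == 31
            (held,) = fold.held_out_compounds
            # Defining exclusion property, re-checked by brute force.
            assert all(held in k for k in fold.validation_keys)
            assert all(held not in k for k in fold.train_keys)
            assert len(fold.train_keys) + len(fold.validation_keys) == 496

    def test_each_record_in_exactly_two_validation_sets(self, full_screen):
        folds = cs.one_compound_out_folds(full_screen["training"], full_screen["records"])
        seen = {}
        for fold in folds:
            for k in fold.validation_keys:
                seen[k] = seen.get(k, 0) + 1
        assert set(seen.values()) == {2}

    def test_unknown_compound_rejected(self, small_screen):
        with pytest.raises(ValueError):
            cs.one_compound_out_folds(small_screen["training"][:3], small_screen["records"])


class TestEverythingOutFolds:
    def test_two_equal_groups_on_full_screen(self, full_screen):
        folds = cs.everything_out_folds(full_screen["training"], full_screen["records"], n_groups=2, seed=0)
        assert [len(f.validation_keys) for f in folds] == [120, 120]  # C(16,2)

    def test_no_compound_shared_between_train_and_validation(self, full_screen):
        for fold in cs.everything_out_folds(full_screen["training"], full_screen["records"], 4, seed=1):
            val_compounds = {c for k in fold.validation_keys for c in k}
            train_compounds = {c for k in fold.train_keys for c in k}
            assert not val_compounds & train_compounds

    def test_seeded_determinism(self, small_screen):
        args = (small_screen["training"], small_screen["records"], 3)
        f1 = cs.everything_out_folds(*args, seed=5)
        f2 = cs.everything_out_folds(*args, seed=5)
        assert [f.validation_keys for f in f1] == [f.validation_keys for f in f2]


class TestYRandomize:
    def test_label_multiset_preserved(self, small_screen):
        records = small_screen["records"]
        permuted = cs.y_randomize(records, seed=3)
        assert sorted(r.gamma_mean for r in permuted) == sorted(r.gamma_mean for r in records)
        assert sum(r.label for r in permuted) == sum(r.label for r in records)
        assert [r.key for r in permuted] == [r.key for r in records]

    def test_seeded_determinism(self, small_screen):
        a = cs.y_randomize(small_screen["records"], seed=8)
        b = cs.y_randomize(small_screen["records"], seed=8)
        assert [r.gamma_mean for r in a] == [r.gamma_mean for r in b]


# Confusion counts printed in the study's retrospective evaluation of 88
# combinations, with the derived metric cells they report.
RETROSPECTIVE_ROWS = {
    "rf_consensus": (ConfusionCounts(tp=40, tn=15, fp=22, fn=11),
                     {"sens": 0.78, "spec": 0.41, "ppv": 0.65, "npv": 0.58, "bacc": 0.59}),
    "tiered_models": (ConfusionCounts(tp=50, tn=0, fp=37, fn=1),
                      {"sens": 0.98, "spec": 0.0, "ppv": 0.57, "npv": 0.0, "bacc": 0.49}),
    "graph_model": (ConfusionCounts(tp=51, tn=2, fp=35, fn=0),
                    {"sens": 1.0, "spec": 0.05, "ppv": 0.59, "npv": 1.0, "bacc": 0.53}),
}


class TestConfusionMetrics:
    @pytest.mark.parametrize("name", sorted(RETROSPECTIVE_ROWS))
    def test_reported_table_cells(self, name):
        counts, expected = RETROSPECTIVE_ROWS[name]
        got = confusion_metrics(counts).rounded(2)
        for metric, value in expected.items():
            assert got[metric] == pytest.approx(value), metric

    def test_matches_brute_force_from_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        labels = rng.random(200) < 0.4
        counts = cs.confusion_from_scores(scores, labels, threshold=0.5)
        m = confusion_metrics(counts)
        # independent recomputation straight from the raw lists
        tp = sum(1 for s, y in zip(scores, labels) if s >= 0.5 and y)
        fn = sum(1 for s, y in zip(scores, labels) if s < 0.5 and y)
        tn = sum(1 for s, y in zip(scores, labels) if s < 0.5 and not y)
        fp = sum(1 for s, y in zip(scores, labels) if s >= 0.5 and not y)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)
        assert m.sens == pytest.approx(tp / (tp + fn))
        assert m.spec == pytest.approx(tn / (tn + fp))

    def test_undefined_ratio_is_missing_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m.ppv)  # 0/0
        assert math.isnan(m.sens)
        assert m.spec == 1.0

    def test_rounding_half_away_from_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=1, tn=1, fp=3, fn=3))  # ratios 0.25
        assert m.rounded(1)["sens"] == 0.3


class TestRocAuc:
    def test_hand_case_by_pair_enumeration(self):
        scores, labels = [0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]
        wins = ties = 0
        for (sp, yp), (sn, yn) in itertools.product(zip(scores, labels), repeat=2):
            if yp == 1 and yn == 0:
                wins += sp > sn
                ties += sp == sn
        expected = (wins + 0.5 * ties) / (sum(labels) * (len(labels) - sum(labels)))
        assert expected == 0.75
        assert roc_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(500)
        labels = rng.random(500) < 0.3
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_is_missing(self):
        assert math.isnan(roc_auc([0.1, 0.2], [1, 1]))


class TestHitRate:
    @pytest.mark.parametrize("hits,percent", [(25, 83), (16, 53), (12, 40)])
    def test_reported_hit_rates(self, hits, percent):
        keys = [cs.make_key(f"a{i}", f"b{i}") for i in range(30)]
        truth = {k: i < hits for i, k in enumerate(keys)}
        assert hit_rate(keys, truth) == pytest.approx(hits / 30)
        assert hit_rate_percent(keys, truth) == percent

    def test_missing_truth_entry_rejected(self):
        keys = [cs.make_key("a", "b")]
        with pytest.raises(KeyError):
            hit_rate(keys, {})
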
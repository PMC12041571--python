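"""Learners, consensus rules, and the Bliss-residual surrogate."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import combisyn as cs
from combisyn.models import DegenerateTrainingError, LearnerSpec


def toy_problem(n=120, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.random((n, 10)).astype(np.float32)
    y = (x[:, 0] + x[:, 1] > 1.0).astype(int)
    keys = [cs.make_key(f"a{i}", f"b{i}") for i in range(n)]
    return x, y, keys


class TestFitPredict:
    @pytest.mark.parametrize("algorithm", ["bagged_trees", "boosted_trees"])
    def test_separable_problem_learned(self, algorithm):
        x, y, keys = toy_problem()
        spec = LearnerSpec(algorithm=algorithm, hyperparameters={"n_estimators": 50})
        ps = cs.fit_predict(spec, x, y, x, keys, seed=0)
        assert cs.roc_auc([ps.scores[k] for k in keys], y) > 0.95

    def test_tree_learners_deterministic_under_seed(self):
        x, y, keys = toy_problem()
        spec = LearnerSpec(hyperparameters={"n_estimators": 20})
        a = cs.fit_predict(spec, x, y, x, keys, seed=5)
        b = cs.fit_predict(spec, x, y, x, keys, seed=5)
        assert a.scores == b.scores

    def test_constant_features_uninformative(self):
        x, y, keys = toy_problem()
        x0 = np.zeros_like(x)
        ps = cs.fit_predict(LearnerSpec(hyperparameters={"n_estimators": 20}), x0, y, x0, keys, seed=1)
        auc = cs.roc_auc([ps.scores[k] for k in keys], y)
        assert 0.35 < auc < 0.65

    def test_single_class_rejected(self):
        x, _, keys = toy_problem()
        with pytest.raises(DegenerateTrainingError):
            cs.fit_predict(LearnerSpec(), x, np.ones(len(x)), x, keys)

    def test_feedforward_net_runs_at_small_scale(self):
        x, y, keys = toy_problem(n=60)
        spec = LearnerSpec(
            algorithm="feedforward_net",
            hyperparameters={"hidden_layer_sizes": (16, 8), "max_iter": 30},
        )
        ps = cs.fit_predict(spec, x, y, x[:5], keys[:5], seed=0)
        assert all(0 <= v <= 1 for v in ps.scores.values())


class TestPseudoProbability:
    def test_minmax_flip_example(self):
        keys = [cs.make_key("a", "x"), cs.make_key("b", "x"), cs.make_key("c", "x")]
        preds = dict(zip(keys, [0.5, 1.0, 1.5]))
        out = cs.regression_to_pseudo_probability(preds)
        assert [out.scores[k] for k in keys] == [1.0, 0.5, 0.0]

    def test_rank_inversion_exact(self):
        rng = np.random.default_rng(2)
        keys = [cs.make_key(f"a{i}", "x") for i in range(50)]
        preds = dict(zip(keys, rng.normal(1.0, 0.2, 50)))
        out = cs.regression_to_pseudo_probability(preds)
        rho = spearmanr([preds[k] for k in keys], [out.scores[k] for k in keys]).statistic
        assert rho == pytest.approx(-1.0)

    def test_all_equal_rejected(self):
        keys = [cs.make_key("a", "x"), cs.make_key("b", "x")]
        with pytest.raises(ValueError):
            cs.regression_to_pseudo_probability(dict.fromkeys(keys, 1.0))


class TestConsensusRules:
    def _sets(self, scores_list):
        keys = [cs.make_key(f"a{i}", "z") for i in range(len(scores_list[0]))]
        return [
            cs.PredictionSet(model_id=f"m{j}", scores=dict(zip(keys, vals)))
            for j, vals in enumerate(scores_list)
        ], keys

    def test_average_and_permutation_invariance(self):
        sets, keys = self._sets([[0.2, 0.9], [0.8, 0.1]])
        avg = cs.average_consensus(sets)
        assert [avg.scores[k] for k in keys] == [0.5, 0.5]
        assert cs.average_consensus(sets[::-1]).scores == avg.scores

    def test_majority_vote_and_tie_rule(self):
        sets, keys = self._sets([[0.9, 0.1, 0.6], [0.8, 0.2, 0.4], [0.1, 0.3, 0.9]])
        votes = cs.majority_vote(sets)
        assert votes[keys[0]] is True and votes[keys[1]] is False
        two, keys2 = self._sets([[0.9], [0.1]])
        assert cs.majority_vote(two)[keys2[0]] is True  # even split -> synergistic

    def test_key_mismatch_rejected(self):
        s1 = cs.PredictionSet("a", {cs.make_key("a", "b"): 0.5})
        s2 = cs.PredictionSet("b", {cs.make_key("a", "c"): 0.5})
        with pytest.raises(ValueError):
            cs.average_consensus([s1, s2])


class TestBlissResidual:
    def test_identities(self):
        assert cs.bliss_residual_score(0.75, 0.5, 0.5) == pytest.approx(0.0)
        assert cs.bliss_residual_score(1.0, 0.0, 0.0) == 1.0
        assert cs.bliss_residual_score(0.0, 1.0, 1.0) == -1.0

    def test_matches_dose_response_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            s_a, s_b = rng.random(2)
            c = float(cs.bliss_expected(s_a, s_b))
            assert cs.bliss_residual_score(c, s_a, s_b) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bliss_residual_score(1.2, 0.5, 0.5)


class TestSurrogateModel:
    def test_zero_synergy_truth_gives_centered_residuals(self, small_screen):
        import dataclasses

        truth = cs.TruthModel(moa_pair_effect={}, replicate_noise_sd=0, compound_noise_sd=0)
        records, _ = cs.simulate_screen(small_screen["training"], truth, with_matrices=False)
        singles, combos = cs.surrogate_training_tables(small_screen["training"], records)
        model = cs.surrogate_combo_model(small_screen["training"], singles, combos, seed=0, epochs=200)
        by_id = {c.id: c for c in small_screen["training"]}
        residuals = list(model.score_pairs([r.key for r in records], by_id).values())
        assert abs(float(np.mean(residuals))) < 0.05

    def test_deterministic_under_seed(self, small_screen):
        records = small_screen["records"]
        singles, combos = cs.surrogate_training_tables(small_screen["training"], records)
        by_id = {c.id: c for c in small_screen["training"]}
        keys = [r.key for r in records][:10]
        s1 = cs.surrogate_combo_model(small_screen["training"], singles, combos, seed=4, epochs=100).score_pairs(keys, by_id)
        s2 = cs.surrogate_combo_model(small_screen["training"], singles, combos, seed=4, epochs=100).score_pairs(keys, by_id)
        assert s1 == s2

    def test_empty_task_data_rejected(self, small_screen):
        with pytest.raises(ValueError):
            cs.surrogate_combo_model(small_screen["training"], {}, {})

    def test_graph_encoder_runs(self, small_screen):
        records = small_screen["records"]
        singles, combos = cs.surrogate_training_tables(small_screen["training"], records)
        model = cs.surrogate_combo_model(
            small_screen["training"], singles, combos, encoder="graph_conv", seed=0, epochs=50
        )
        by_id = {c.id: c for c in small_screen["training"]}
        pred = model.predict_pair(small_screen["training"][0], small_screen["training"][1])
        assert 0 <= pred.c_ab <= 1 and -1 <= pred.synergy_score <= 1

    def test_learns_synergy_on_mechanism_truth(self, small_screen):
        """On MoA-driven truth the Bliss residual ranks synergistic pairs higher."""
        res = cs.evaluate_surrogate(small_screen["training"], small_screen["records"], seed=1)
        assert res["test_auc"] > 0.5
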
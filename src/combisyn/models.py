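"""Base learners, consensus score combination, and the Bliss-residual surrogate.

Two families of synergy scorers live here:

* conventional pair-feature learners (random forest, gradient boosting,
  feed-forward net) producing classifier probabilities or regression
  pseudo-probabilities, combined by averaging or majority vote;
* a multi-task surrogate that encodes each molecule, predicts single-agent
  inhibition s(A), s(B) and combination inhibition c(AB), and scores
  synergy as the residual over Bliss independence,
  c(AB) - [s(A) + s(B) - s(A)s(B)], higher meaning more synergistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import CombinationKey
from .doseresponse import DEFAULT_KAPPA, bliss_expected, hill_response
from .featurize import _atom_features, _require_mol, compound_descriptor
from .validate import roc_auc


class DegenerateTrainingError(ValueError):
    """Training labels contain a single class."""


@dataclass(frozen=True)
class PredictionSet:
    """Scores per canonical pair, in [0, 1] with higher = more synergistic."""

    model_id: str
    scores: dict
    kind: str = "classifier_probability"

    def __post_init__(self):
        for k, v in self.scores.items():
            if not isinstance(k, CombinationKey):
                raise TypeError(f"score key {k!r} is not a CombinationKey")
            if not math.isfinite(v):
                raise ValueError(f"non-finite score for {k}")


@dataclass(frozen=True)
class LearnerSpec:
    """A base learner: algorithm family, task, and hyperparameter overrides.

    Defaults follow the study's settings where stated (boosted-tree
    learning rate 0.01; feed-forward layers 700/500/300, Adam, learning
    rate 1e-4, batch 128, 70 epochs).
    """

    algorithm: str = "bagged_trees"
    task: str = "classify"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in ("bagged_trees", "boosted_trees", "feedforward_net"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.task not in ("classify", "regress"):
            raise ValueError(f"task must be 'classify' or 'regress', got {self.task!r}")


def _make_estimator(spec: LearnerSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "bagged_trees":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        if spec.task == "classify":
            return RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 100), random_state=seed, n_jobs=1, **hp
            )
        return RandomForestRegressor(
            n_estimators=hp.pop("n_estimators", 100),
            max_features=hp.pop("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
            **hp,
        )
    if spec.algorithm == "boosted_trees":
        from xgboost import XGBClassifier, XGBRegressor

        kwargs = dict(
            n_estimators=hp.pop("n_estimators", 200),
            learning_rate=hp.pop("learning_rate", 0.01),
            max_depth=hp.pop("max_depth", 4),
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
        )
        kwargs.update(hp)
        return XGBClassifier(**kwargs) if spec.task == "classify" else XGBRegressor(**kwargs)
    from sklearn.neural_network import MLPClassifier, MLPRegressor

    kwargs = dict(
        hidden_layer_sizes=hp.pop("hidden_layer_sizes", (700, 500, 300)),
        solver="adam",
        learning_rate_init=hp.pop("learning_rate_init", 1e-4),
        batch_size=hp.pop("batch_size", 128),
        max_iter=hp.pop("max_iter", 70),
        random_state=seed,
    )
    kwargs.update(hp)
    cls = MLPClassifier if spec.task == "classify" else MLPRegressor
    return cls(**kwargs)


def fit_predict(
    spec: LearnerSpec,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    test_keys,
    seed: int = 0,
    model_id: str | None = None,
) -> PredictionSet:
    """Fit one learner and emit a prediction set over ``test_keys``.

    Classifiers emit class-1 probabilities; regressors emit raw gamma
    predictions (kind ``regression_raw``) to be converted downstream by
    :func:`regression_to_pseudo_probability`.
    """
    y_train = np.asarray(y_train)
    if spec.task == "classify":
        classes = np.unique(y_train)
        if len(classes) < 2:
            raise DegenerateTrainingError("classifier training labels contain a single class")
    est = _make_estimator(spec, seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence at fixed small epoch budget
        est.fit(x_train, y_train.astype(int) if spec.task == "classify" else y_train)
    if spec.task == "classify":
        probs = est.predict_proba(x_test)[:, 1]
        kind = "classifier_probability"
    else:
        probs = est.predict(x_test)
        kind = "regression_raw"
    name = model_id or f"{spec.algorithm}-{spec.task}"
    return PredictionSet(model_id=name, scores=dict(zip(test_keys, map(float, probs))), kind=kind)


def regression_to_pseudo_probability(predictions: dict | PredictionSet, model_id: str | None = None) -> PredictionSet:
    """Min-max scale predicted gammas over the batch and flip (1 - scaled).

    The minimum gamma maps to 1.0 (most synergistic), the maximum to 0.0.
    Raises when all predictions are equal (scale undefined).
    """
    if isinstance(predictions, PredictionSet):
        scores, name = predictions.scores, predictions.model_id
    else:
        scores, name = predictions, model_id or "regression"
    values = np.array(list(scores.values()), dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("all predictions equal; min-max scale undefined")
    out = {k: float(1.0 - (v - lo) / (hi - lo)) for k, v in scores.items()}
    return PredictionSet(model_id=name + "-pseudo", scores=out, kind="regression_pseudo_probability")


def _check_shared_keys(sets):
    if not sets:
        raise ValueError("no prediction sets given")
    keys = set(sets[0].scores)
    for s in sets[1:]:
        if set(s.scores) != keys:
            raise ValueError(f"prediction set {s.model_id!r} covers different keys")
    return keys


def average_consensus(sets, model_id: str = "consensus") -> PredictionSet:
    """Per-key arithmetic mean of the member scores."""
    keys = _check_shared_keys(sets)
    scores = {k: float(np.mean([s.scores[k] for s in sets])) for k in keys}
    return PredictionSet(model_id=model_id, scores=scores, kind="consensus")


def majority_vote(sets, threshold: float = 0.5) -> dict:
    """Per-key majority of (score >= threshold) calls; even splits vote synergistic."""
    keys = _check_shared_keys(sets)
    out = {}
    for k in keys:
        votes = sum(1 for s in sets if s.scores[k] >= threshold)
        out[k] = votes * 2 >= len(sets)
    return out


def bliss_residual_score(c_ab: float, s_a: float, s_b: float) -> float:
    """Observed combination inhibition minus its Bliss expectation, in [-1, 1]."""
    for name, v in (("c_ab", c_ab), ("s_a", s_a), ("s_b", s_b)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return float(c_ab - bliss_expected(s_a, s_b))


# ---------------------------------------------------------------------------
# Multi-task Bliss-residual surrogate (shared molecule encoder, two heads)
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _graph_embedding(mol, dim: int, rounds: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed random-weight message passing with sum pooling.

    Serves as an untrained graph-convolution feature map: node features are
    mixed over ``rounds`` neighbourhood aggregations with fixed seeded
    weights, then sum-pooled and squashed.
    """
    from rdkit import Chem

    feats = _atom_features(mol)
    adj = Chem.GetAdjacencyMatrix(mol).astype(float) + np.eye(mol.GetNumAtoms())
    adj = adj / adj.sum(axis=1, keepdims=True)
    w_in = rng.normal(0, 1.0 / np.sqrt(feats.shape[1]), size=(feats.shape[1], dim))
    h = np.maximum(feats @ w_in, 0.0)
    for _ in range(rounds):
        w = rng.normal(0, 1.0 / np.sqrt(dim), size=(dim, dim))
        h = np.maximum(adj @ h @ w, 0.0)
    pooled = h.sum(axis=0) / np.sqrt(mol.GetNumAtoms())
    return np.tanh(pooled)


@dataclass
class ComboPrediction:
    s_a: float
    s_b: float
    c_ab: float
    synergy_score: float


class SurrogateComboModel:
    """Small multi-task network scoring synergy as the Bliss residual.

    A shared encoder maps each molecule to a hidden vector; a single-agent
    head predicts s(.) and a combination head predicts c(.,.) from the
    symmetric sum of the two hidden vectors, both squashed to [0, 1].
    Synergy is scored as c(AB) - [s(A)+s(B)-s(A)s(B)].

    ``encoder`` is either ``fingerprint_mlp`` (Morgan bits into a trainable
    hidden layer, the default desk-scale choice) or ``graph_conv`` (a fixed
    seeded random-weight message-passing embedding feeding the same
    trainable heads).  Training is full-batch Adam on the joint MSE of the
    two tasks; fully deterministic under a fixed seed.
    """

    def __init__(
        self,
        encoder: str = "fingerprint_mlp",
        hidden: int = 64,
        combo_hidden: int = 32,
        epochs: int = 400,
        learning_rate: float = 0.01,
        fingerprint_bits: int = 1024,
        graph_rounds: int = 3,
        single_task_weight: float = 1.0,
        seed: int = 0,
    ):
        if encoder not in ("fingerprint_mlp", "graph_conv"):
            raise ValueError(f"unknown encoder {encoder!r}")
        self.encoder = encoder
        self.hidden = hidden
        self.combo_hidden = combo_hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.fingerprint_bits = fingerprint_bits
        self.graph_rounds = graph_rounds
        self.single_task_weight = single_task_weight
        self.seed = seed
        self._params = None
        self._inputs: dict = {}

    # -- encoding -----------------------------------------------------------

    def _encode_input(self, compound) -> np.ndarray:
        if compound.id in self._inputs:
            return self._inputs[compound.id]
        if self.encoder == "fingerprint_mlp":
            vec = compound_descriptor(compound, f"morgan-{self.fingerprint_bits}").values
        else:
            rng = np.random.default_rng(self.seed + 7)
            vec = _graph_embedding(_require_mol(compound), self.hidden, self.graph_rounds, rng)
        self._inputs[compound.id] = vec
        return vec

    # -- training -----------------------------------------------------------

    def fit(self, compounds, single_targets: dict, combo_targets: dict) -> "SurrogateComboModel":
        """Train on single-agent inhibition targets and pair inhibition targets.

        ``single_targets``: compound id -> inhibition in [0, 1];
        ``combo_targets``: CombinationKey -> combination inhibition in [0, 1].
        """
        if not single_targets or not combo_targets:
            raise ValueError("both single-agent and combination task data are required")
        by_id = {c.id: c for c in compounds}
        mol_ids = sorted(by_id)
        idx = {cid: i for i, cid in enumerate(mol_ids)}
        x = np.stack([self._encode_input(by_id[cid]) for cid in mol_ids])
        s_ids = [cid for cid in mol_ids if cid in single_targets]
        s_rows = np.array([idx[cid] for cid in s_ids])
        s_t = np.array([single_targets[cid] for cid in s_ids], dtype=float)
        pair_keys = sorted(combo_targets)
        ia = np.array([idx[k.first] for k in pair_keys])
        ib = np.array([idx[k.second] for k in pair_keys])
        c_t = np.array([combo_targets[k] for k in pair_keys], dtype=float)

        rng = np.random.default_rng(self.seed)
        d, h, h2 = x.shape[1], self.hidden, self.combo_hidden
        params = {
            "W1": rng.normal(0, 1.0 / np.sqrt(d), (d, h)),
            "b1": np.zeros(h),
            "ws": rng.normal(0, 1.0 / np.sqrt(h), h),
            "bs": 0.0,
            "W2": rng.normal(0, 1.0 / np.sqrt(h), (h, h2)),
            "b2": np.zeros(h2),
            "wc": rng.normal(0, 1.0 / np.sqrt(h2), h2),
            "bc": 0.0,
        }
        m_adam = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
        v_adam = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        sw = self.single_task_weight

        for step in range(1, self.epochs + 1):
            hid = np.maximum(x @ params["W1"] + params["b1"], 0.0)
            # single-agent head
            s_pre = hid[s_rows] @ params["ws"] + params["bs"]
            s_hat = _sigmoid(s_pre)
            # combination head over the symmetric sum of hidden vectors
            h_pair = hid[ia] + hid[ib]
            z = np.maximum(h_pair @ params["W2"] + params["b2"], 0.0)
            c_pre = z @ params["wc"] + params["bc"]
            c_hat = _sigmoid(c_pre)

            d_spre = sw * (2.0 / len(s_t)) * (s_hat - s_t) * s_hat * (1 - s_hat)
            d_cpre = (2.0 / len(c_t)) * (c_hat - c_t) * c_hat * (1 - c_hat)

            grads = {
                "ws": hid[s_rows].T @ d_spre,
                "bs": d_spre.sum(),
                "wc": z.T @ d_cpre,
                "bc": d_cpre.sum(),
            }
            d_z = np.outer(d_cpre, params["wc"]) * (z > 0)
            grads["W2"] = h_pair.T @ d_z
            grads["b2"] = d_z.sum(axis=0)
            d_hid = np.zeros_like(hid)
            np.add.at(d_hid, s_rows, np.outer(d_spre, params["ws"]))
            d_hpair = d_z @ params["W2"].T
            np.add.at(d_hid, ia, d_hpair)
            np.add.at(d_hid, ib, d_hpair)
            d_pre1 = d_hid * (hid > 0)
            grads["W1"] = x.T @ d_pre1
            grads["b1"] = d_pre1.sum(axis=0)

            for k in params:
                g = grads[k]
                m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * g
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * np.square(g)
                m_hat = m_adam[k] / (1 - beta1 ** step)
                v_hat = v_adam[k] / (1 - beta2 ** step)
                params[k] = params[k] - self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        self._params = params
        return self

    # -- inference ----------------------------------------------------------

    def _hidden(self, compound) -> np.ndarray:
        p = self._params
        return np.maximum(self._encode_input(compound) @ p["W1"] + p["b1"], 0.0)

    def predict_single(self, compound) -> float:
        if self._params is None:
            raise RuntimeError("model is not fitted")
        p = self._params
        return float(_sigmoid(self._hidden(compound) @ p["ws"] + p["bs"]))

    def predict_pair(self, a, b) -> ComboPrediction:
        if self._params is None:
            raise RuntimeError("model is not fitted")
        p = self._params
        ha, hb = self._hidden(a), self._hidden(b)
        z = np.maximum((ha + hb) @ p["W2"] + p["b2"], 0.0)
        c_ab = float(_sigmoid(z @ p["wc"] + p["bc"]))
        s_a, s_b = self.predict_single(a), self.predict_single(b)
        return ComboPrediction(s_a=s_a, s_b=s_b, c_ab=c_ab, synergy_score=bliss_residual_score(c_ab, s_a, s_b))

    def score_pairs(self, keys, compounds_by_id: dict) -> dict:
        """Bliss-residual synergy scores per key (range [-1, 1])."""
        return {
            k: self.predict_pair(compounds_by_id[k.first], compounds_by_id[k.second]).synergy_score
            for k in keys
        }

    def to_prediction_set(self, keys, compounds_by_id: dict, model_id: str = "surrogate") -> PredictionSet:
        """Residual scores rescaled from [-1, 1] to [0, 1] for consensus use."""
        raw = self.score_pairs(keys, compounds_by_id)
        return PredictionSet(
            model_id=model_id,
            scores={k: (v + 1.0) / 2.0 for k, v in raw.items()},
            kind="bliss_residual_rescaled",
        )


def surrogate_combo_model(
    compounds,
    single_targets: dict,
    combo_targets: dict,
    encoder: str = "fingerprint_mlp",
    seed: int = 0,
    **kwargs,
) -> SurrogateComboModel:
    """Build and train a :class:`SurrogateComboModel` (functional wrapper)."""
    model = SurrogateComboModel(encoder=encoder, seed=seed, **kwargs)
    return model.fit(compounds, single_targets, combo_targets)


def surrogate_training_tables(
    actives,
    records,
    kappa: float = DEFAULT_KAPPA,
    slope: float = 1.0,
    e_max: float = 0.7,
) -> tuple:
    """Single-agent and combination inhibition targets from a screen.

    Single-agent target: the compound's Hill inhibition at its mid-grid
    dose (index 6, i.e. IC50 * sqrt(2)).  Combination target: the Bliss
    composition of those margins plus the excess kappa*(1 - gamma_mean),
    clipped to [0, 1] — the matched-dose cell of the simulated block.
    """
    singles = {}
    for c in actives:
        ic50 = 10.0 ** c.log_ic50
        singles[c.id] = float(hill_response(ic50 * math.sqrt(2.0), ic50, slope, e_max))
    combos = {}
    for r in records:
        s_a, s_b = singles[r.key.first], singles[r.key.second]
        combos[r.key] = float(np.clip(bliss_expected(s_a, s_b) + kappa * (1.0 - r.gamma_mean), 0.0, 1.0))
    return singles, combos


def evaluate_surrogate(
    actives,
    records,
    seed: int = 0,
    encoder: str = "fingerprint_mlp",
    splits=(0.8, 0.1, 0.1),
    **model_kwargs,
) -> dict:
    """Train/validation/test experiment for the surrogate on one screen.

    Records are split at random (seeded) into train/validation/test
    fractions; the model trains on the training combinations (plus all
    single-agent targets) and is scored by ROC AUC of its Bliss-residual
    score against the gamma < 0.95 synergy label on the held-out test set.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(splits[0] * len(records)))
    n_val = int(round(splits[1] * len(records)))
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train:n_train + n_val]]
    test = [records[i] for i in order[n_train + n_val:]]
    singles, combos_all = surrogate_training_tables(actives, records)
    combos_train = {r.key: combos_all[r.key] for r in train}
    model = surrogate_combo_model(actives, singles, combos_train, encoder=encoder, seed=seed, **model_kwargs)
    by_id = {c.id: c for c in actives}

    def auc_of(subset):
        scores = model.score_pairs([r.key for r in subset], by_id)
        return roc_auc([scores[r.key] for r in subset], [r.label for r in subset])

    return {
        "model": model,
        "test_auc": auc_of(test),
        "validation_auc": auc_of(val) if val else math.nan,
        "n_train": len(train),
        "n_test": len(test),
    }


# ---------------------------------------------------------------------------
# Cross-validated consensus over pair-feature learners
# ---------------------------------------------------------------------------

#: The default consensus: random-forest classification averaged with
#: random-forest regression pseudo-probabilities.  50 trees is a desk-scale
#: choice: with ~500 training pairs the cross-validated AUC plateaus well
#: below this forest size.
DEFAULT_LEARNERS = (
    LearnerSpec(algorithm="bagged_trees", task="classify", hyperparameters={"n_estimators": 50}),
    LearnerSpec(algorithm="bagged_trees", task="regress", hyperparameters={"n_estimators": 50}),
)


@dataclass(frozen=True)
class CrossValResult:
    fold_aucs: tuple
    mean_auc: float
    oof_scores: dict  # key -> mean out-of-fold consensus score


def consensus_fit_predict(
    learners,
    x_train: np.ndarray,
    y_label_train: np.ndarray,
    y_gamma_train: np.ndarray,
    x_test: np.ndarray,
    test_keys,
    seed: int = 0,
) -> PredictionSet:
    """Fit each learner and average their probabilities over the test keys.

    Classifiers train on the binary synergy label; regressors train on
    gamma and are converted to pseudo-probabilities over the test batch.
    """
    sets = []
    for i, spec in enumerate(learners):
        y = y_label_train if spec.task == "classify" else y_gamma_train
        ps = fit_predict(spec, x_train, y, x_test, test_keys, seed=seed + i)
        if ps.kind == "regression_raw":
            ps = regression_to_pseudo_probability(ps)
        sets.append(ps)
    return average_consensus(sets)


def cross_validate_consensus(
    x: np.ndarray,
    labels: np.ndarray,
    gammas: np.ndarray,
    keys,
    folds,
    learners=DEFAULT_LEARNERS,
    seed: int = 0,
) -> CrossValResult:
    """Consensus AUC across pre-built folds over a fixed design matrix."""
    row = {k: i for i, k in enumerate(keys)}
    labels = np.asarray(labels, dtype=bool)
    gammas = np.asarray(gammas, dtype=float)
    fold_aucs = []
    oof: dict = {}
    for fold in folds:
        tr = np.array([row[k] for k in fold.train_keys])
        va = np.array([row[k] for k in fold.validation_keys])
        if len(va) == 0 or len(np.unique(labels[tr])) < 2:
            continue
        ps = consensus_fit_predict(
            learners, x[tr], labels[tr], gammas[tr], x[va], list(fold.validation_keys), seed=seed
        )
        scores = np.array([ps.scores[k] for k in fold.validation_keys])
        auc = roc_auc(scores, labels[va])
        if math.isfinite(auc):
            fold_aucs.append(auc)
        for k, s in ps.scores.items():
            oof.setdefault(k, []).append(s)
    mean_auc = float(np.mean(fold_aucs)) if fold_aucs else math.nan
    return CrossValResult(
        fold_aucs=tuple(fold_aucs),
        mean_auc=mean_auc,
        oof_scores={k: float(np.mean(v)) for k, v in oof.items()},
    )
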
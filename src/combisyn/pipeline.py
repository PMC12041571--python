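"""End-to-end driver: simulate -> featurize -> cross-validate -> score ->
nominate -> evaluate -> network analysis, with a manifest for reproducibility.

All randomness flows from one root seed, split per stage, so a run is
reproducible from a single integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .core import enumerate_pairs
from .featurize import build_design_matrix
from .models import (
    DEFAULT_LEARNERS,
    LearnerSpec,
    consensus_fit_predict,
    cross_validate_consensus,
)
from .moanet import build_network, empirical_significance, permutation_null
from .nominate import TierParams, diversity_capped_topk, synergistic_moa_pairs, tiered_nomination, topk_nomination
from .synthdata import (
    ScreenConfig,
    TruthModel,
    calibrate_noise,
    default_truth,
    generate_library,
    moa_vocabulary,
    replicate_pearson,
    simulate_screen,
    true_label,
)
from .validate import confusion_from_scores, confusion_metrics, hit_rate, one_compound_out_folds

logger = logging.getLogger("combisyn")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; unknown names fail fast at construction."""

    screen: ScreenConfig = field(default_factory=lambda: ScreenConfig(n_extra_active=150))
    truth: TruthModel | None = None
    calibrate_replicates: bool = False
    target_pearson: float = 0.83
    descriptor: str = "morgan-1024"
    composition: str = "average"
    use_moa_vector: bool = True
    use_potency: bool = False
    learners: tuple = DEFAULT_LEARNERS
    n_virtual_pairs: int = 20000
    k_nominations: int = 30
    per_compound_cap: int = 5
    tier_params: TierParams = field(default_factory=TierParams)
    network_cutoffs: tuple = (0.95, 0.5)
    n_permutations: int = 1000
    write_matrices: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        nested = {"screen": ScreenConfig, "truth": TruthModel, "tier_params": TierParams}
        for name, sub_cls in nested.items():
            if name in data:
                sub = data.pop(name)
                known = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(sub) - known
                if unknown:
                    raise ValueError(f"unknown {name} fields: {sorted(unknown)}")
                kwargs[name] = sub_cls(**sub)
        if "learners" in data:
            specs = []
            for item in data.pop("learners"):
                known = {f.name for f in dataclasses.fields(LearnerSpec)}
                unknown = set(item) - known
                if unknown:
                    raise ValueError(f"unknown learner fields: {sorted(unknown)}")
                specs.append(LearnerSpec(**item))
            kwargs["learners"] = tuple(specs)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # partial outputs stay on disk
                logger.error("stage %s: failed (%s)", name, exc)
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, output_dir) -> Path:
    """Execute the full workflow and write all artifacts under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(8)]
    metrics: dict = {"seed": config.seed}

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def simulate():
        library = generate_library(config.screen, seed=seeds[0])
        truth = config.truth if config.truth is not None else default_truth(seed=seeds[1])
        if config.calibrate_replicates:
            truth = calibrate_noise(truth, config.target_pearson, seed=seeds[2], actives=training)
        training = [c for c in library if c.in_training]
        records, matrices = simulate_screen(
            training, truth, seed=seeds[1],
            n_replicates=config.screen.n_replicates,
            with_matrices=config.write_matrices,
        )
        cio.write_compounds(library, out / "compounds.csv")
        cio.write_combinations(records, out / "combinations.csv")
        if config.write_matrices:
            cio.write_matrices(matrices, out / "matrices.csv")
        return library, truth, records

    library, truth, records = simulate()
    by_id = {c.id: c for c in library}
    training = [c for c in library if c.in_training]
    vocab = moa_vocabulary(config.screen.n_moas) if config.use_moa_vector else None
    metrics["n_library"] = len(library)
    metrics["n_training_combinations"] = len(records)
    metrics["synergistic_fraction"] = float(np.mean([r.label for r in records]))
    metrics["replicate_pearson"] = replicate_pearson(records)

    # -- featurize + cross-validate ---------------------------------------
    @_stage("cross_validate")
    def cross_validate():
        keys = [r.key for r in records]
        x = build_design_matrix(
            keys, by_id, config.descriptor, config.composition, vocab, config.use_potency
        )
        labels = np.array([r.label for r in records])
        gammas = np.array([r.gamma_mean for r in records])
        folds = one_compound_out_folds(training, records)
        cv = cross_validate_consensus(x, labels, gammas, keys, folds, config.learners, seed=seeds[3])
        oof = [cv.oof_scores[k] for k in keys]
        counts = confusion_from_scores(oof, labels, threshold=0.5)
        report = confusion_metrics(counts)
        metrics["cv_mean_auc"] = cv.mean_auc
        metrics["cv_auc_sd"] = float(np.std(cv.fold_aucs)) if cv.fold_aucs else math.nan
        metrics["cv_metrics"] = report.rounded()
        metrics["cv_counts"] = dataclasses.asdict(counts)
        return x, labels, gammas, keys

    x_train, labels, gammas, train_keys = cross_validate()

    # -- score virtual library --------------------------------------------
    @_stage("score")
    def score():
        virtual = enumerate_pairs(library, exclude=set(train_keys))
        metrics["n_virtual_pairs_total"] = len(virtual)
        rng = np.random.default_rng(seeds[4])
        if config.n_virtual_pairs < len(virtual):
            idx = rng.choice(len(virtual), size=config.n_virtual_pairs, replace=False)
            pool = [virtual[i] for i in sorted(idx)]
        else:
            pool = virtual
        x_pool = build_design_matrix(
            pool, by_id, config.descriptor, config.composition, vocab, config.use_potency
        )
        consensus = consensus_fit_predict(
            config.learners, x_train, labels, gammas, x_pool, pool, seed=seeds[5]
        )
        # Descriptor-only scores (no MoA block) for the tiered strategy.
        x_train_d = build_design_matrix(train_keys, by_id, config.descriptor, config.composition)
        x_pool_d = build_design_matrix(pool, by_id, config.descriptor, config.composition)
        descriptor_only = consensus_fit_predict(
            config.learners, x_train_d, labels, gammas, x_pool_d, pool, seed=seeds[5]
        )
        cio.write_predictions(consensus, out / "predictions_consensus.csv")
        cio.write_predictions(descriptor_only, out / "predictions_descriptor_only.csv")
        return pool, consensus, descriptor_only

    pool, consensus, descriptor_only = score()

    # -- nominate + evaluate against synthetic truth -----------------------
    @_stage("nominate")
    def nominate():
        primary_moa = {c.id: c.primary_moa for c in library}
        moa_table = synergistic_moa_pairs([r for r in records], primary_moa)
        lists = {
            "topk": topk_nomination(consensus, k=config.k_nominations, name="topk"),
            "diversity": diversity_capped_topk(
                consensus, k=config.k_nominations, per_compound_cap=config.per_compound_cap, name="diversity"
            ),
            "tiered": tiered_nomination(
                consensus, descriptor_only, library, moa_table,
                moa_map=primary_moa, params=config.tier_params, name="tiered",
            ),
        }
        truth_labels = {
            k: true_label(by_id[k.first], by_id[k.second], truth) for nl in lists.values() for k in nl.keys
        }
        metrics["hit_rates"] = {}
        for name, nl in lists.items():
            cio.write_nominations(nl, out / f"nominations_{name}.csv")
            if nl.entries:
                metrics["hit_rates"][name] = hit_rate(nl.keys, truth_labels)
        metrics["n_moa_pairs_selected"] = len(moa_table.selected)
        return lists

    nominate()

    # -- MoA network --------------------------------------------------------
    @_stage("network")
    def network():
        moa_map = {c.id: c.moa_labels for c in library}
        for cutoff in config.network_cutoffs:
            net = build_network(records, moa_map, gamma_cutoff=cutoff)
            tag = str(cutoff).replace(".", "")
            if net.edges:
                cio.write_network_edges(net, out / f"moa_network_{tag}.tsv")
                cio.write_network_graphml(net, out / f"moa_network_{tag}.graphml")
        net = build_network(records, moa_map, gamma_cutoff=0.95)
        if net.edges:
            top_edge, observed = max(net.edges.items(), key=lambda kv: (kv[1], kv[0]))
            synergistic = [r for r in records if r.label]
            pool_ids = sorted({cid for r in synergistic for cid in (r.key.first, r.key.second)})
            null = permutation_null(
                pool_ids, moa_map, n_combos=len(synergistic),
                n_reps=config.n_permutations, seed=seeds[6],
            )
            sig = empirical_significance(observed, null.per_pair_counts.get(top_edge, np.zeros(config.n_permutations)))
            metrics["top_moa_edge"] = {
                "edge": list(top_edge),
                "observed": sig.observed,
                "null_mean": sig.null_mean,
                "null_sd": sig.null_sd,
                "p_value": sig.p_value,
                "p_normal": sig.p_normal,
            }

    network()

    # -- manifest -----------------------------------------------------------
    import rdkit
    import sklearn

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)
    cio.write_manifest(
        {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "stage_seeds": ",".join(map(str, seeds)),
            "numpy_version": np.__version__,
            "sklearn_version": sklearn.__version__,
            "rdkit_version": rdkit.__version__,
        },
        out / "manifest.txt",
    )
    return out
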
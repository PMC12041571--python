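"""Synthetic combination screen with a known mechanism-level ground truth.

Emulates a MIPE-like anticancer screen: a 1785-compound annotated library,
32 single-agent actives with log10(IC50) in [-8.7, -5.5], all-vs-all
duplicate 10x10 combination blocks, and gamma-style synergy labels.  The
ground truth is mechanistic: specific unordered MoA-label pairs carry a
negative additive effect that pulls gamma below the 0.95 synergy cutoff,
so every downstream stage can be tested against a recoverable truth.

Structures are drawn from a bundled list of drug-like scaffolds keyed to
the compound's primary MoA, so that (as in real libraries) compounds
sharing a mechanism are structurally related and structure-based models
can learn mechanism-driven synergy.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .core import Compound, SynergyRecord, enumerate_pairs, moa_pair
from .doseresponse import DEFAULT_KAPPA, simulate_matrix

# Drug-like scaffolds; each stays chemically valid when suffixed with the
# alkyl/alcohol decorations below (verified by the test suite).
SCAFFOLD_SMILES = (
    "CC(=O)Nc1ccc(O)cc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2nc3ccccc3nc2c1",
    "O=C(O)c1ccccc1O",
    "c1ccc(-c2ccccn2)cc1",
    "O=C1CCCCN1c1ccccc1",
    "CN1CCN(c2ccccc2)CC1",
    "O=C(Nc1ccccc1)c1ccccc1",
    "c1ccc(Oc2ccccc2)cc1",
    "CC1=CC(=O)CC(C)(C)C1",
    "O=C1Nc2ccccc2N1",
    "c1ccc(CN2CCCC2)cc1",
    "O=S(=O)(N)c1ccc(N)cc1",
    "Cc1ccc2nc(N)sc2c1",
    "O=C(O)CCc1ccccc1",
    "c1cnc2[nH]ccc2c1",
    "COc1ccc(CCN)cc1",
    "O=C1CCC(=O)N1",
    "c1ccc(-n2cncn2)cc1",
    "CC(=O)c1ccc(N)cc1",
    "O=C(Cc1ccccc1)NO",
    "c1ccc(CSc2ccccn2)cc1",
    "CN(C)c1ccc(C=O)cc1",
    "Oc1ccc2ccccc2c1",
    "Nc1ccc(N)nc1",
    "O=C(O)c1cccnc1",
    "CC1CCC(=O)N1c1ccccc1",
    "c1ccc(N2CCOCC2)cc1",
    "OCc1ccc(Cl)cc1",
    "N#Cc1ccc(O)cc1",
    "O=C(NO)c1ccc(N)cc1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "c1ccc(-c2nnc(S)o2)cc1",
    "NC(=O)c1ccccc1N",
    "O=C(Nc1ccncc1)C1CC1",
    "COc1cc2c(cc1OC)CCN2",
    "Oc1ccc(CC2CCNCC2)cc1",
    "O=C1CSC(c2ccccc2)N1",
    "Cc1ccc2[nH]ccc2c1",
)

DECORATIONS = ("", "C", "CC", "CCC", "CCCC", "CO", "CCO", "CCCO")

# Field-style names for the mechanisms carried by the active compounds.
ACTIVE_MOA_LABELS = (
    "proteasome inhibitor",
    "HDAC inhibitor",
    "PLK1 inhibitor",
    "mTOR inhibitor",
    "mutant-p53 activator",
    "survivin inhibitor",
    "tubulin polymerization inhibitor",
    "topoisomerase II inhibitor",
)

# Ground-truth synergistic mechanism pairs: additive shifts applied to the
# baseline gamma of any combination whose cross-compound MoA pairs include
# them.  Calibrated so the simulated screen reproduces a ~52% synergistic
# fraction and replicate Pearson correlation near 0.83.
DEFAULT_MOA_EFFECTS = {
    moa_pair("proteasome inhibitor", "HDAC inhibitor"): -0.45,
    moa_pair("proteasome inhibitor", "PLK1 inhibitor"): -0.30,
    moa_pair("proteasome inhibitor", "mutant-p53 activator"): -0.25,
    moa_pair("HDAC inhibitor", "survivin inhibitor"): -0.30,
    moa_pair("HDAC inhibitor", "topoisomerase II inhibitor"): -0.30,
    moa_pair("mTOR inhibitor", "mutant-p53 activator"): -0.25,
    moa_pair("PLK1 inhibitor", "tubulin polymerization inhibitor"): -0.35,
}


class CalibrationError(RuntimeError):
    """Raised when a replicate-correlation target cannot be reached."""


def moa_vocabulary(n_moas: int) -> tuple:
    """Ordered MoA vocabulary: named active mechanisms first, then generic labels."""
    named = ACTIVE_MOA_LABELS[:n_moas]
    generic = tuple(f"moa-{i:04d}" for i in range(len(named), n_moas))
    return named + generic


@dataclass(frozen=True)
class ScreenConfig:
    """Shape of the emulated screen (defaults follow the reference assay)."""

    n_active: int = 32
    n_library: int = 1785
    n_moas: int = 821
    log_ic50_range: tuple = (-8.7, -5.5)
    n_replicates: int = 2
    n_active_moas: int = 8
    second_moa_prob: float = 0.3
    # Extra library compounds flagged active but kept out of training; 0 by
    # default so exactly n_active compounds carry the active flag.
    n_extra_active: int = 0

    def __post_init__(self):
        if self.n_active + self.n_extra_active > self.n_library:
            raise ValueError("active compounds cannot exceed the library size")
        lo, hi = self.log_ic50_range
        if not lo < hi:
            raise ValueError("log_ic50_range bounds must be ordered")
        if self.n_active_moas > self.n_moas:
            raise ValueError("active MoA vocabulary cannot exceed the full vocabulary")


@dataclass(frozen=True)
class TruthModel:
    """Generative model for gamma: baseline + MoA-pair effects + noise.

    ``compound_noise_sd`` is pair-level (shared between replicates, e.g.
    reproducible off-mechanism biology); ``replicate_noise_sd`` is per
    replicate and controls replicate-to-replicate agreement.
    """

    moa_pair_effect: dict = field(default_factory=lambda: dict(DEFAULT_MOA_EFFECTS))
    baseline_gamma_mean: float = 1.0
    replicate_noise_sd: float = 0.07
    compound_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.replicate_noise_sd < 0 or self.compound_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for pair, eff in self.moa_pair_effect.items():
            if not math.isfinite(eff):
                raise ValueError(f"effect for {pair} must be finite")


def default_truth(seed: int = 0) -> TruthModel:
    return TruthModel(seed=seed)


def _pair_effect(labels_a, labels_b, effects) -> float:
    total = 0.0
    for la in labels_a:
        for lb in labels_b:
            total += effects.get(moa_pair(la, lb), 0.0)
    return total


def true_gamma(a: Compound, b: Compound, truth: TruthModel) -> float:
    """Noiseless gamma implied by the truth model for the pair (a, b)."""
    g = truth.baseline_gamma_mean + _pair_effect(a.moa_labels, b.moa_labels, truth.moa_pair_effect)
    return float(np.clip(g, 0.0, 2.0))


def true_label(a: Compound, b: Compound, truth: TruthModel) -> bool:
    from .core import label_synergy

    return label_synergy(true_gamma(a, b, truth))


def generate_library(config: ScreenConfig = ScreenConfig(), seed: int = 0) -> list:
    """Deterministic synthetic compound library.

    The first ``n_active`` compounds are the screen actives (flagged
    ``in_training``); each compound carries 1-2 MoA labels, actives drawn
    from the small active vocabulary so mechanisms recur across compounds.
    """
    if not SCAFFOLD_SMILES:
        raise RuntimeError("bundled scaffold list is empty")
    rng = np.random.default_rng(seed)
    vocab = moa_vocabulary(config.n_moas)
    active_vocab = vocab[: config.n_active_moas]
    scaffold_of = {label: SCAFFOLD_SMILES[i % len(SCAFFOLD_SMILES)] for i, label in enumerate(vocab)}
    lo, hi = config.log_ic50_range
    compounds = []
    for i in range(config.n_library):
        training = i < config.n_active
        active = i < config.n_active + config.n_extra_active
        if training:
            primary = active_vocab[i % len(active_vocab)]
        elif active:
            primary = active_vocab[int(rng.integers(len(active_vocab)))]
        else:
            primary = vocab[int(rng.integers(len(vocab)))]
        labels = {primary}
        if rng.random() < config.second_moa_prob:
            pool = active_vocab if training else vocab
            labels.add(pool[int(rng.integers(len(pool)))])
        log_ic50 = float(rng.uniform(lo, hi)) if active else math.nan
        smiles = scaffold_of[primary] + DECORATIONS[i % len(DECORATIONS)]
        compounds.append(
            Compound(
                id=f"CMP-{i:04d}",
                smiles=smiles,
                log_ic50=log_ic50,
                moa_labels=frozenset(labels),
                is_active=active,
                in_training=training,
            )
        )
    return compounds


def simulate_screen(
    actives: list,
    truth: TruthModel,
    seed: int | None = None,
    n_replicates: int = 2,
    with_matrices: bool = True,
    matrix_noise_sd: float = 0.01,
    kappa: float = DEFAULT_KAPPA,
) -> tuple:
    """All-vs-all duplicate screen over ``actives``.

    Per pair: gamma = baseline + sum of MoA-pair effects over the label
    cross-product + shared pair noise; each replicate adds independent
    replicate noise; gammas are clipped to [0, 2].  Returns
    ``(records, matrices)``; matrices embed the same gammas as excess-Bliss
    inhibition via :func:`combisyn.doseresponse.simulate_matrix`.
    """
    for c in actives:
        if not c.is_active:
            raise ValueError(f"compound {c.id!r} is not flagged active")
    root = np.random.SeedSequence(truth.seed if seed is None else seed)
    gamma_ss, matrix_ss = root.spawn(2)
    rng = np.random.default_rng(gamma_ss)
    # Separate stream for matrix noise so records are identical whether or
    # not matrices are generated.
    rng_m = np.random.default_rng(matrix_ss)
    by_id = {c.id: c for c in actives}
    records, matrices = [], []
    for key in enumerate_pairs(actives):
        a, b = by_id[key.first], by_id[key.second]
        base = (
            truth.baseline_gamma_mean
            + _pair_effect(a.moa_labels, b.moa_labels, truth.moa_pair_effect)
            + rng.normal(0.0, truth.compound_noise_sd)
        )
        reps = np.clip(base + rng.normal(0.0, truth.replicate_noise_sd, n_replicates), 0.0, 2.0)
        records.append(SynergyRecord.from_replicates(key, reps))
        if with_matrices:
            for r, g in enumerate(reps, start=1):
                matrices.append(
                    simulate_matrix(
                        a, b, float(g),
                        noise_sd=matrix_noise_sd,
                        seed=int(rng_m.integers(2 ** 31)),
                        replicate=r,
                        kappa=kappa,
                    )
                )
    return records, matrices


def replicate_pearson(records: list) -> float:
    """Pearson correlation between the first two replicates across records."""
    r1 = np.array([r.gamma_replicates[0] for r in records])
    r2 = np.array([r.gamma_replicates[1] for r in records])
    if np.std(r1) == 0 or np.std(r2) == 0:
        return math.nan
    return float(np.corrcoef(r1, r2)[0, 1])


def calibrate_noise(
    truth: TruthModel,
    target_pearson: float = 0.83,
    n_pairs: int = 496,
    seed: int = 0,
    tol: float = 0.02,
    actives: list | None = None,
) -> TruthModel:
    """Bisect ``replicate_noise_sd`` so simulated replicate correlation hits the target.

    Calibrate on the screen's own ``actives`` when given — the shared
    (effect + pair-noise) variance depends on the MoA composition, so the
    achieved correlation tracks the target best on the same compounds.
    Raises :class:`CalibrationError` when the screen's gammas carry no
    shared variance (correlation undefined) or the target is outside (0, 1).
    """
    if not 0 < target_pearson < 1:
        raise CalibrationError("target correlation must lie strictly between 0 and 1")
    if actives is None:
        n_active = 2
        while n_active * (n_active - 1) // 2 < n_pairs:
            n_active += 1
        cfg = ScreenConfig(n_active=n_active, n_library=n_active)
        actives = generate_library(cfg, seed=seed)

    def corr_at(sd: float) -> float:
        trial = dataclasses.replace(truth, replicate_noise_sd=sd)
        records, _ = simulate_screen(actives, trial, seed=seed, with_matrices=False)
        return replicate_pearson(records[:n_pairs])

    base_corr = corr_at(0.0)
    if not math.isfinite(base_corr):
        raise CalibrationError("gammas have no shared variance; correlation is undefined")
    lo, hi = 0.0, 0.25
    while corr_at(hi) > target_pearson:
        hi *= 2
        if hi > 16:
            raise CalibrationError("replicate noise cannot push correlation to the target")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        c = corr_at(mid)
        if abs(c - target_pearson) < tol / 2:
            lo = hi = mid
            break
        if c > target_pearson:
            lo = mid
        else:
            hi = mid
    sd = 0.5 * (lo + hi)
    return dataclasses.replace(truth, replicate_noise_sd=sd)
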
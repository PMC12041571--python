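import numpy as np
import pytest
from hypothesis import settings

import combisyn as cs

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_screen():
    """12-active screen with 4 active MoAs; fast enough for most unit tests."""
    cfg = cs.ScreenConfig(n_active=12, n_library=40, n_moas=24, n_active_moas=4)
    library = cs.generate_library(cfg, seed=7)
    training = [c for c in library if c.in_training]
    truth = cs.default_truth(seed=7)
    records, matrices = cs.simulate_screen(training, truth, seed=7)
    return {
        "config": cfg,
        "library": library,
        "training": training,
        "truth": truth,
        "records": records,
        "matrices": matrices,
    }


@pytest.fixture(scope="session")
def full_screen():
    """The default 32-active screen with replicate noise calibrated to r ~ 0.83."""
    cfg = cs.ScreenConfig()
    library = cs.generate_library(cfg, seed=11)
    training = [c for c in library if c.in_training]
    truth = cs.calibrate_noise(cs.default_truth(seed=11), target_pearson=0.83, seed=11, actives=training)
    records, _ = cs.simulate_screen(training, truth, seed=11, with_matrices=False)
    return {
        "config": cfg,
        "library": library,
        "training": training,
        "truth": truth,
        "records": records,
    }


@pytest.fixture(scope="session")
def full_design(full_screen):
    """Design matrix, labels and folds for the full screen (shared across tests)."""
    lib = full_screen["library"]
    records = full_screen["records"]
    by_id = {c.id: c for c in lib}
    vocab = cs.moa_vocabulary(full_screen["config"].n_moas)
    keys = [r.key for r in records]
    x = cs.build_design_matrix(keys, by_id, "morgan-1024", "average", vocab)
    folds = cs.one_compound_out_folds(full_screen["training"], records)
    return {
        "x": x,
        "keys": keys,
        "labels": np.array([r.label for r in records]),
        "gammas": np.array([r.gamma_mean for r in records]),
        "folds": folds,
    }
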
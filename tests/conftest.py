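"""Shared fixtures: synthetic cohorts and trained models.

The expensive artifacts (the 23-subject cohort, the cross-validated
training runs, a quick single-fold model) are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from afedge import cnn, dataset, pipeline, quantize, synthetic

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort():
    """23-subject synthetic cohort at generator defaults."""
    store, manifest = synthetic.gen_cohort(n_subjects=23, seed=COHORT_SEED)
    return store, manifest


@pytest.fixture(scope="session")
def e2e_results(cohort):
    """Full 5-fold cross-validated runs at N = 25 and N = 100."""
    store, _ = cohort
    return pipeline.run_experiment(store, (25, 100), seed=COHORT_SEED, keep_models=True)


@pytest.fixture(scope="session")
def quick_model(cohort):
    """One trained N=25 model (fold 1) plus its data splits, for fast reuse."""
    store, _ = cohort
    folds = dataset.assign_folds(sorted(store), seed=COHORT_SEED)
    bundle = dataset.build_bundle(store, 25, folds, seed=COHORT_SEED)
    x = np.stack([s.features for s in bundle.train_tables[1]])
    y = np.array([s.label for s in bundle.train_tables[1]])
    x_te = np.stack([s.features for s in bundle.test_tables[1]])
    y_te = np.array([s.label for s in bundle.test_tables[1]])
    tc = cnn.TrainConfig(seed=COHORT_SEED, max_epochs=30)
    x_tr, y_tr, x_va, y_va = cnn.split_train_val(x, y, tc.val_fraction, tc.seed)
    model = cnn.build_model(cnn.ModelConfig(n=25), seed=COHORT_SEED)
    tm = cnn.train(model, (x_tr, y_tr), (x_va, y_va), tc)
    qm = quantize.quantize_int8(tm, x_tr, seed=COHORT_SEED)
    return {
        "trained": tm,
        "quantized": qm,
        "x_train": x_tr,
        "x_test": x_te,
        "y_test": y_te,
    }


class StubModel:
    """predict_proba stub with a fixed AF probability (stream plumbing tests)."""

    def __init__(self, af_probability: float):
        self.af_probability = af_probability

    def predict_proba(self, windows):
        windows = np.asarray(windows)
        p = np.full((len(windows), 2), 1.0 - self.af_probability)
        p[:, 1] = self.af_probability
        return p


@pytest.fixture
def af_stub_model():
    return StubModel(0.93)


@pytest.fixture
def sr_stub_model():
    return StubModel(0.04)
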
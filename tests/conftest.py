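import numpy as np
import pytest

import fatiguegcn as fg
from fatiguegcn.cases import select_case


def make_case_dataset(case_id: str, n_per_class: int = 100, seed: int = 0):
    """Normalized, relabeled dataset for one classification case."""
    case = fg.define_case(case_id)
    specs = fg.default_class_specs()
    cohort = fg.CohortSpec(
        classes=[specs[c] for c in case.class_subset],
        n_windows_per_class=n_per_class,
        seed=seed,
    )
    ds = select_case(fg.generate_cohort(cohort), case_id)
    return fg.normalize_dataset(ds), case


def train_case(case_id: str, seed: int, epochs: int = 30, n_per_class: int = 100):
    """Full desk-scale training run; returns (trained, splits, case)."""
    ds, case = make_case_dataset(case_id, n_per_class, seed)
    tr, va, te = fg.split_dataset(ds, seed=seed)
    g = fg.build_channel_graph(tr, threshold=0.3)
    spec = fg.reduced_architecture(n_classes=case.n_classes)
    model = fg.build_model(spec, g, seed=seed)
    cfg = fg.TrainConfig(learning_rate=3e-3, epochs=epochs, seed=seed)
    trained = fg.train(model, tr, va, cfg)
    return trained, (tr, va, te), case


@pytest.fixture(scope="session")
def two_class_splits():
    ds, _ = make_case_dataset("I", 100, seed=0)
    return fg.split_dataset(ds, seed=0)


@pytest.fixture(scope="session")
def trained_two_class(two_class_splits):
    """One trained 2-class model shared by prediction/robustness tests."""
    tr, va, te = two_class_splits
    g = fg.build_channel_graph(tr, threshold=0.3)
    spec = fg.reduced_architecture(n_classes=2)
    model = fg.build_model(spec, g, seed=0)
    trained = fg.train(model, tr, va, fg.TrainConfig(learning_rate=3e-3, epochs=30, seed=0))
    return trained


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
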
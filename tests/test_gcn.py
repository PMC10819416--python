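"""Classifier: parameter accounting, model contracts, splitting, training."""

import numpy as np
import pytest

import fatiguegcn as fg
from fatiguegcn.containers import WindowedDataset
from fatiguegcn.gcn import GCNModel, LayerSpec, _batched_eval
from fatiguegcn.graph import ChannelGraph, normalized_laplacian, scaled_laplacian
from fatiguegcn.nn import ChebGraphConv

from conftest import make_case_dataset


def graph_from_adjacency(A, threshold=0.0):
    L = normalized_laplacian(A)
    Lt, lam = scaled_laplacian(L)
    return ChannelGraph(A, threshold, lam, L, Lt)


def ring_graph(n=4):
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
    return graph_from_adjacency(A)


class TestCountParameters:
    def test_full_scale_replica_matches_published_table(self):
        spec = fg.full_scale_architecture()
        rows = fg.count_parameters(spec)["layers"]
        per_order = [r["weights_per_order"] for r in rows if r["layer"].startswith("conv")]
        assert per_order == [8_526_400, 4_263_200, 1_065_800, 266_450, 65_700]
        assert spec.flatten_dim == 720
        fc = rows[-1]
        assert fc["weights"] + fc["bias"] == 2_880 + 4

    def test_empty_spec_counts_zero(self):
        spec = fg.ArchitectureSpec(layers=(), n_nodes=4, n_classes=2)
        assert fg.count_parameters(spec)["total"] == 0

    def test_matches_brute_force_enumeration_random_specs(self, rng):
        """Analytic table vs sum of instantiated trainable array sizes."""
        g = ring_graph(4)
        for _ in range(200):
            n_layers = int(rng.integers(1, 4))
            widths = rng.integers(1, 9, size=n_layers + 1)
            cheb = rng.integers(1, 4, size=n_layers)
            bn = bool(rng.integers(0, 2))
            layers = tuple(
                LayerSpec(cheb_order=int(cheb[i]), in_features=int(widths[i]),
                          out_features=int(widths[i + 1]), batch_norm=bn)
                for i in range(n_layers)
            )
            spec = fg.ArchitectureSpec(layers=layers, n_nodes=4,
                                       n_classes=int(rng.integers(2, 6)))
            model = fg.build_model(spec, g, seed=0)
            assert model.n_parameters() == fg.count_parameters(spec)["total"]


class TestBuildModel:
    def test_probabilities_sum_to_one(self, rng):
        spec = fg.reduced_architecture(widths=(8, 8, 8, 8, 8), n_classes=3,
                                       front_end="none", in_features=20)
        model = fg.build_model(spec, ring_graph(), seed=0)
        p = model.predict_proba(rng.standard_normal((2, 4, 20)))
        assert p.shape == (2, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_node_count_mismatch_rejected(self):
        spec = fg.reduced_architecture(n_classes=2)
        with pytest.raises(ValueError, match="nodes"):
            fg.build_model(spec, ring_graph(3), seed=0)

    def test_welch_front_end_bin_mismatch_rejected(self):
        layers = (LayerSpec(1, 100, 8),)  # 100 != 250 // 2 + 1
        with pytest.raises(ValueError, match="bins"):
            fg.ArchitectureSpec(layers=layers, front_end="welch", front_end_nperseg=250)

    def test_edgeless_graph_collapses_chebconv_to_dense(self, rng):
        """With L~ = I every T_k = I, so the layer equals a per-node dense map
        with weight sum_k W_k."""
        T = np.stack([np.eye(4)] * 3)  # edgeless: scaled Laplacian is identity
        layer = ChebGraphConv(T, 6, 5, rng)
        X = rng.standard_normal((2, 4, 6))
        expected = X @ layer.W.value.sum(axis=0) + layer.b.value
        np.testing.assert_allclose(layer.forward(X), expected, atol=1e-8)

    def test_order_one_layers_are_graph_independent(self, rng):
        """C_k = 1 uses only T_0 = I, so two different graphs give equal output."""
        spec = fg.reduced_architecture(widths=(8, 8, 8, 8, 8), n_classes=2,
                                       cheb=(1, 1, 1, 1, 1),
                                       front_end="none", in_features=20)
        g1 = ring_graph(4)
        A2 = np.zeros((4, 4))
        A2[0, 1] = A2[1, 0] = 1.0
        g2 = graph_from_adjacency(A2)
        m1 = fg.build_model(spec, g1, seed=5)
        m2 = fg.build_model(spec, g2, seed=5)
        X = rng.standard_normal((3, 4, 20))
        np.testing.assert_allclose(m1.predict_proba(X), m2.predict_proba(X), atol=1e-12)


class TestSplitDataset:
    def make_ds(self, per_class, classes=(0, 1)):
        n = per_class * len(classes)
        X = np.random.default_rng(0).standard_normal((n, 2, 10))
        y = np.repeat(classes, per_class)
        ids = [f"c{c}w{i:05d}" for c in classes for i in range(per_class)]
        return WindowedDataset(X, y, ids)

    def test_published_split_arithmetic(self):
        tr, va, te = fg.split_dataset(self.make_ds(2920), seed=0)
        assert (len(tr), len(va), len(te)) == (2 * 2044, 2 * 584, 2 * 292)

    def test_ten_windows_split_7_2_1(self):
        tr, va, te = fg.split_dataset(self.make_ds(10), seed=0)
        assert (len(tr), len(va), len(te)) == (14, 4, 2)
        for part in (tr, va, te):
            counts = part.label_counts()
            assert counts[0] == counts[1]

    def test_partition_is_disjoint_and_complete(self):
        ds = self.make_ds(10)
        tr, va, te = fg.split_dataset(ds, seed=3)
        all_ids = sorted(tr.ids + va.ids + te.ids)
        assert all_ids == sorted(ds.ids)
        assert not (set(tr.ids) & set(va.ids)) and not (set(tr.ids) & set(te.ids))

    def test_order_insensitive_given_seed(self):
        ds = self.make_ds(10)
        shuffled = ds.subset(np.random.default_rng(1).permutation(len(ds)))
        a = fg.split_dataset(ds, seed=5)
        b = fg.split_dataset(shuffled, seed=5)
        for pa, pb in zip(a, b):
            assert sorted(pa.ids) == sorted(pb.ids)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            fg.split_dataset(self.make_ds(2), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            fg.split_dataset(self.make_ds(10), fractions=(0.5, 0.2, 0.2), seed=0)


class TestTraining:
    def test_two_class_cohort_learnable(self, trained_two_class):
        """Validation accuracy >= 0.90 on the separable default cohort."""
        assert max(trained_two_class.history["val_acc"]) >= 0.90

    def test_history_bookkeeping_one_epoch(self, two_class_splits):
        tr, va, _ = two_class_splits
        g = fg.build_channel_graph(tr, threshold=0.3)
        model = fg.build_model(fg.reduced_architecture(n_classes=2), g, seed=0)
        trained = fg.train(model, tr, va, fg.TrainConfig(learning_rate=3e-3, epochs=1, seed=0))
        assert all(len(v) == 1 for v in trained.history.values())
        assert trained.best_epoch == 0

    def test_single_class_labels_rejected(self, two_class_splits):
        tr, va, _ = two_class_splits
        only0 = tr.subset(np.flatnonzero(tr.y == 0))
        g = fg.build_channel_graph(tr, threshold=0.3)
        model = fg.build_model(fg.reduced_architecture(n_classes=2), g, seed=0)
        with pytest.raises(ValueError, match="cover"):
            fg.train(model, only0, va, fg.TrainConfig(epochs=1))

    def test_overfits_sixteen_windows(self, two_class_splits):
        """Capacity check: training loss below 0.05 within 200 epochs."""
        tr, va, _ = two_class_splits
        idx = np.concatenate([np.flatnonzero(tr.y == c)[:8] for c in (0, 1)])
        sub = tr.subset(idx)
        g = fg.build_channel_graph(tr, threshold=0.3)
        model = fg.build_model(fg.reduced_architecture(n_classes=2), g, seed=1)
        trained = fg.train(model, sub, va,
                           fg.TrainConfig(learning_rate=3e-3, epochs=200, batch_size=16, seed=1))
        assert min(trained.history["train_loss"]) < 0.05

    def test_best_weights_retained(self, trained_two_class, two_class_splits):
        _, va, _ = two_class_splits
        acc, _ = _batched_eval(trained_two_class.model, va)
        assert acc == pytest.approx(max(trained_two_class.history["val_acc"]))


class TestPredict:
    def test_inference_deterministic(self, trained_two_class, two_class_splits):
        _, _, te = two_class_splits
        _, p1 = fg.predict(trained_two_class, te)
        _, p2 = fg.predict(trained_two_class, te)
        np.testing.assert_array_equal(p1, p2)

    def test_one_label_per_window(self, trained_two_class, two_class_splits):
        _, _, te = two_class_splits
        labels, probs = fg.predict(trained_two_class, te)
        assert labels.shape == (len(te),)
        assert probs.shape == (len(te), 2)

    def test_generalizes_within_ten_points_of_validation(self, trained_two_class,
                                                         two_class_splits):
        _, _, te = two_class_splits
        val_acc = max(trained_two_class.history["val_acc"])
        test_acc = fg.evaluate_accuracy(trained_two_class, te)
        assert test_acc >= val_acc - 0.10

    def test_feature_length_mismatch_rejected(self, rng):
        spec = fg.reduced_architecture(widths=(8, 8, 8, 8, 8), n_classes=2,
                                       front_end="none", in_features=20)
        model = fg.build_model(spec, ring_graph(), seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            model.forward(rng.standard_normal((2, 4, 19)))


def test_case_one_at_least_as_accurate_as_case_four():
    """Difficulty rises with the number of fatigue stages (2-class vs 5-class)."""
    from conftest import train_case

    wins = 0
    for seed in (0, 1):
        t1, (_, _, te1), _ = train_case("I", seed)
        t4, (_, _, te4), _ = train_case("IV", seed)
        if fg.evaluate_accuracy(t1, te1) >= fg.evaluate_accuracy(t4, te4) - 0.03:
            wins += 1
    assert wins == 2
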
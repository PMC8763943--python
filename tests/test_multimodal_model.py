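"""Encoder training, embeddings, fusion, and the frozen-encoder contract."""

import copy

import numpy as np
import pytest

from metafuse.io_formats import FeatureMatrix
from metafuse.multimodal_model import (
    EncoderConfig,
    concat_embeddings,
    embed,
    load_model,
    predict,
    save_model,
    train_encoder,
    train_fusion,
    train_multimodal,
)
from metafuse.nn import MLP

SMALL = EncoderConfig(hidden_sizes=(32, 16), epochs=30, seed=7)


def _gauss_matrix(n_per_class=20, n_features=30, shift=5.0, seed=0, modality="taxonomic"):
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, size=(2 * n_per_class, n_features))
    z[n_per_class:, :5] += shift
    m = FeatureMatrix(
        tuple(f"s{i}" for i in range(2 * n_per_class)),
        tuple(f"f{j}" for j in range(n_features)),
        z,
        modality,
        "log",
    )
    labels = ["case"] * n_per_class + ["control"] * n_per_class
    return m, labels


class TestTrainEncoder:
    def test_separable_classes_fit_perfectly(self):
        m, labels = _gauss_matrix(shift=5.0)
        enc = train_encoder(m, labels, SMALL)
        assert enc.predict(m) == labels

    def test_same_seed_identical_weights(self):
        m, labels = _gauss_matrix()
        a = train_encoder(m, labels, SMALL)
        b = train_encoder(m, labels, SMALL)
        assert all(np.array_equal(x, y) for x, y in zip(a.net.weights, b.net.weights))
        assert all(np.array_equal(x, y) for x, y in zip(a.net.biases, b.net.biases))

    def test_shuffled_labels_give_chance_holdout_accuracy(self):
        """Permutation null: held-out accuracy near 0.5 averaged over seeds."""
        m, labels = _gauss_matrix(n_per_class=30, shift=5.0, seed=3)
        rng = np.random.default_rng(99)
        accs = []
        for s in range(10):
            perm = list(rng.permutation(labels))
            train_idx = list(range(0, 60, 2))
            test_idx = list(range(1, 60, 2))
            enc = train_encoder(
                m.select_samples(train_idx),
                [perm[i] for i in train_idx],
                EncoderConfig(hidden_sizes=(32, 16), epochs=30, seed=s),
            )
            pred = enc.predict(m.select_samples(test_idx))
            accs.append(np.mean([p == perm[i] for p, i in zip(pred, test_idx)]))
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_single_class_and_nan_rejected(self):
        m, _ = _gauss_matrix(n_per_class=5)
        with pytest.raises(ValueError, match="2 classes"):
            train_encoder(m, ["x"] * m.n_samples, SMALL)
        bad = FeatureMatrix(m.sample_ids, m.feature_ids, m.values.copy(), "taxonomic", "log")
        with pytest.raises(ValueError):
            bad.values[0, 0] = np.nan
            train_encoder(bad, ["a"] * 5 + ["b"] * 5, SMALL)


class TestEmbedding:
    def test_embedding_width_is_last_hidden_size(self):
        m, labels = _gauss_matrix(n_per_class=10)
        enc = train_encoder(m, labels, EncoderConfig(hidden_sizes=(200, 100, 50), epochs=2))
        e = embed(enc, m)
        assert e.n_features == 50
        assert e.modality == "embedding"

    def test_zero_network_zero_embedding(self):
        net = MLP([4, 3, 2], [np.zeros((4, 3)), np.zeros((3, 2))], [np.zeros(3), np.zeros(2)])
        assert np.all(net.embed(np.ones((2, 4))) == 0.0)

    def test_single_sample(self):
        m, labels = _gauss_matrix(n_per_class=10)
        enc = train_encoder(m, labels, SMALL)
        one = m.select_samples([0])
        assert embed(enc, one).values.shape == (1, 16)

    def test_dimension_mismatch_error(self):
        m, labels = _gauss_matrix(n_per_class=10, n_features=30)
        enc = train_encoder(m, labels, SMALL)
        other = FeatureMatrix(m.sample_ids, ("x",), np.zeros((20, 1)), "taxonomic", "log")
        with pytest.raises(ValueError, match="features"):
            embed(enc, other)


class TestConcat:
    def _parts(self, widths, n=4):
        sample_ids = tuple(f"s{i}" for i in range(n))
        return [
            FeatureMatrix(
                sample_ids,
                tuple(f"m{k}_e{j}" for j in range(w)),
                np.random.default_rng(k).normal(size=(n, w)),
                "embedding",
                "log",
            )
            for k, w in enumerate(widths)
        ]

    def test_three_parts_concatenate(self):
        fused = concat_embeddings(self._parts([50, 50, 50]))
        assert fused.n_features == 150
        assert fused.modality == "fused"

    def test_single_part_identity_values(self):
        (p,) = self._parts([7])
        fused = concat_embeddings([p])
        assert np.array_equal(fused.values, p.values)

    def test_sample_order_mismatch_error(self):
        a, b = self._parts([3, 3])
        b_rev = FeatureMatrix(
            tuple(reversed(b.sample_ids)), b.feature_ids, b.values[::-1], "embedding", "log"
        )
        with pytest.raises(ValueError, match="sample ids"):
            concat_embeddings([a, b_rev])


class TestFusionAndPredict:
    def test_two_stage_training_separable(self):
        mats = {
            "taxonomic": _gauss_matrix(seed=1)[0],
            "genomic": _gauss_matrix(seed=2, modality="genomic")[0],
        }
        labels = _gauss_matrix()[1]
        model = train_multimodal(
            mats, labels,
            encoder_configs={k: SMALL for k in mats},
            fusion_config=EncoderConfig(hidden_sizes=(50, 25), epochs=30, seed=11),
        )
        proba = predict(model, mats)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        pred = [model.classes[i] for i in proba.argmax(axis=1)]
        assert pred == labels  # memorization on separable training data

    def test_fusion_training_leaves_encoders_frozen(self):
        mats = {"taxonomic": _gauss_matrix(seed=1)[0]}
        labels = _gauss_matrix()[1]
        enc = train_encoder(mats["taxonomic"], labels, SMALL)
        before_w = [w.copy() for w in enc.net.weights]
        fused = concat_embeddings([embed(enc, mats["taxonomic"])])
        train_fusion(fused, labels, EncoderConfig(hidden_sizes=(50, 25), epochs=20, seed=3))
        assert all(np.array_equal(a, b) for a, b in zip(before_w, enc.net.weights))

    def test_softmax_rows_normalize_for_random_inputs(self, rng):
        net = MLP.init([10, 8, 3], seed=0)
        proba = net.predict_proba(rng.normal(size=(50, 10)))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert proba.min() >= 0

    def test_sample_permutation_invariance_of_metrics(self):
        """Reordering samples (with labels) without shuffling preserves accuracy."""
        m, labels = _gauss_matrix(n_per_class=15, shift=2.0, seed=5)
        cfg = EncoderConfig(hidden_sizes=(32, 16), epochs=30, seed=7, batch_size=64, shuffle=False)
        enc = train_encoder(m, labels, cfg)
        acc = np.mean([p == t for p, t in zip(enc.predict(m), labels)])
        perm = list(np.random.default_rng(0).permutation(m.n_samples))
        m2 = m.select_samples(perm)
        labels2 = [labels[i] for i in perm]
        enc2 = train_encoder(m2, labels2, cfg)
        acc2 = np.mean([p == t for p, t in zip(enc2.predict(m2), labels2)])
        assert acc == acc2


def test_model_save_load_roundtrip(tmp_path):
    mats = {"taxonomic": _gauss_matrix(seed=1)[0], "genomic": _gauss_matrix(seed=2, modality="genomic")[0]}
    labels = _gauss_matrix()[1]
    model = train_multimodal(
        mats, labels,
        encoder_configs={k: SMALL for k in mats},
        fusion_config=EncoderConfig(hidden_sizes=(50, 25), epochs=5, seed=1),
    )
    save_model(model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert np.array_equal(predict(model, mats), predict(back, mats))
    assert back.classes == model.classes
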
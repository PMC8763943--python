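"""Two-stage multimodal classifier with late fusion.

Stage one trains an independent feedforward encoder per modality on the
class labels; the activations of each encoder's last hidden layer are its
embedded representation of the modality.  Stage two concatenates the
embeddings into a shared representation and trains a small fusion classifier
on it; the encoders stay frozen.  Default architectures: 200-100-50 hidden
nodes for the taxonomic and genomic encoders, 500-100-50 for the (wider)
functional encoder, and 50-25 for the fusion network.  All nets use ReLU
hiddens, a softmax output and Adam (lr 0.001, beta_1 0.9, beta_2 0.999).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_formats import FeatureMatrix
from .nn import MLP

DEFAULT_HIDDEN = {
    "taxonomic": (200, 100, 50),
    "genomic": (200, 100, 50),
    "functional": (500, 100, 50),
}
FUSION_HIDDEN = (50, 25)


@dataclass
class EncoderConfig:
    hidden_sizes: tuple[int, ...] = (200, 100, 50)
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 0.001
    beta_1: float = 0.9
    beta_2: float = 0.999
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty with all sizes >= 1")

    def with_seed(self, seed: int) -> "EncoderConfig":
        return replace(self, seed=int(seed))


@dataclass
class EncoderModel:
    """Trained per-modality network; embedding = last hidden layer."""

    net: MLP
    classes: tuple[str, ...]
    feature_ids: tuple[str, ...]
    modality: str
    config: EncoderConfig

    @property
    def embedding_dim(self) -> int:
        return self.net.layer_sizes[-2]

    def predict_proba(self, m: FeatureMatrix) -> np.ndarray:
        _check_features(self, m)
        return self.net.predict_proba(m.values)

    def predict(self, m: FeatureMatrix) -> list[str]:
        proba = self.predict_proba(m)
        return [self.classes[i] for i in proba.argmax(axis=1)]


@dataclass
class MultimodalModel:
    """Per-modality encoders plus the fusion classifier over their embeddings."""

    encoders: dict[str, EncoderModel]
    fusion: EncoderModel
    classes: tuple[str, ...]
    modality_order: tuple[str, ...]


def _check_features(e: EncoderModel, m: FeatureMatrix) -> None:
    if m.n_features != e.net.layer_sizes[0]:
        raise ValueError(
            f"matrix has {m.n_features} features, encoder expects {e.net.layer_sizes[0]}"
        )


def _one_hot(labels: Sequence[str], classes: tuple[str, ...]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y


def train_encoder(m: FeatureMatrix, labels: Sequence[str], cfg: EncoderConfig) -> EncoderModel:
    """Train one modality's encoder network on the class labels.

    Deterministic for a fixed config seed: the seed controls both weight
    init and the per-epoch minibatch order.
    """
    if m.transform != "log":
        raise ValueError("encoders expect log-transformed input (transform='log')")
    if len(labels) != m.n_samples:
        raise ValueError(f"{len(labels)} labels for {m.n_samples} samples")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    if np.isnan(m.values).any():
        raise ValueError("NaN in feature matrix")
    sizes = [m.n_features, *cfg.hidden_sizes, len(classes)]
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2) % (2**31)
    net = MLP.init(sizes, seed=int(seeds[0]))
    net.fit(
        m.values,
        _one_hot(labels, classes),
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        beta_1=cfg.beta_1,
        beta_2=cfg.beta_2,
        seed=int(seeds[1]),
        shuffle=cfg.shuffle,
    )
    return EncoderModel(net, classes, m.feature_ids, m.modality, cfg)


def embed(e: EncoderModel, m: FeatureMatrix) -> FeatureMatrix:
    """Last-hidden-layer activations as a new FeatureMatrix (modality='embedding')."""
    _check_features(e, m)
    emb = e.net.embed(m.values)
    feature_ids = tuple(f"{e.modality}_emb{i}" for i in range(emb.shape[1]))
    return FeatureMatrix(m.sample_ids, feature_ids, emb, "embedding", "log")


def concat_embeddings(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of embeddings into the shared representation."""
    if not parts:
        raise ValueError("no embeddings to concatenate")
    sample_ids = parts[0].sample_ids
    for p in parts[1:]:
        if p.sample_ids != sample_ids:
            raise ValueError("sample ids/order differ between embedding parts")
    feature_ids = tuple(f for p in parts for f in p.feature_ids)
    values = np.concatenate([p.values for p in parts], axis=1)
    return FeatureMatrix(sample_ids, feature_ids, values, "fused", "log")


def train_fusion(
    fused: FeatureMatrix, labels: Sequence[str], cfg: EncoderConfig | None = None
) -> EncoderModel:
    """Train the stage-two classifier on the fused representation."""
    if cfg is None:
        cfg = EncoderConfig(hidden_sizes=FUSION_HIDDEN)
    if fused.modality != "fused":
        raise ValueError("train_fusion expects a fused matrix from concat_embeddings")
    return train_encoder(
        FeatureMatrix(fused.sample_ids, fused.feature_ids, fused.values, "fused", "log"),
        labels,
        cfg,
    )


def train_multimodal(
    matrices: Mapping[str, FeatureMatrix],
    labels: Sequence[str],
    encoder_configs: Mapping[str, EncoderConfig] | None = None,
    fusion_config: EncoderConfig | None = None,
    seed: int = 0,
) -> MultimodalModel:
    """Full two-stage training: encoders per modality, then frozen-encoder fusion.

    Modalities are processed in the given mapping order; each network gets an
    independent seed derived from ``seed`` unless an explicit config is
    supplied for it.
    """
    if not matrices:
        raise ValueError("no modalities given")
    order = tuple(matrices)
    ss = np.random.SeedSequence(seed).generate_state(len(order) + 1) % (2**31)
    encoders: dict[str, EncoderModel] = {}
    for k, name in enumerate(order):
        m = matrices[name]
        if encoder_configs and name in encoder_configs:
            cfg = encoder_configs[name]
        else:
            hidden = DEFAULT_HIDDEN.get(m.modality, (200, 100, 50))
            cfg = EncoderConfig(hidden_sizes=hidden, seed=int(ss[k]))
        encoders[name] = train_encoder(m, labels, cfg)
    fused = concat_embeddings([embed(encoders[name], matrices[name]) for name in order])
    if fusion_config is None:
        fusion_config = EncoderConfig(hidden_sizes=FUSION_HIDDEN, seed=int(ss[-1]))
    fusion = train_fusion(fused, labels, fusion_config)
    return MultimodalModel(encoders, fusion, fusion.classes, order)


def predict(model: MultimodalModel, matrices: Mapping[str, FeatureMatrix]) -> np.ndarray:
    """Class probabilities for one or more samples, rows summing to 1."""
    missing = [n for n in model.modality_order if n not in matrices]
    if missing:
        raise ValueError(f"missing modalities: {missing}")
    parts = [embed(model.encoders[n], matrices[n]) for n in model.modality_order]
    fused = concat_embeddings(parts)
    return model.fusion.net.predict_proba(fused.values)


def predict_labels(model: MultimodalModel, matrices: Mapping[str, FeatureMatrix]) -> list[str]:
    proba = predict(model, matrices)
    return [model.classes[i] for i in proba.argmax(axis=1)]


# ---------------------------------------------------------------------------
# Persistence: config as YAML, weights as .npz alongside


def save_model(model: MultimodalModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "classes": list(model.classes),
        "modality_order": list(model.modality_order),
        "networks": {},
    }

    def _dump(name: str, enc: EncoderModel) -> None:
        arrays = {}
        for i, (W, b) in enumerate(zip(enc.net.weights, enc.net.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(out / f"{name}.npz", **arrays)
        meta["networks"][name] = {
            "layer_sizes": list(enc.net.layer_sizes),
            "modality": enc.modality,
            "feature_ids": list(enc.feature_ids),
            "config": {
                "hidden_sizes": list(enc.config.hidden_sizes),
                "epochs": enc.config.epochs,
                "batch_size": enc.config.batch_size,
                "learning_rate": enc.config.learning_rate,
                "beta_1": enc.config.beta_1,
                "beta_2": enc.config.beta_2,
                "seed": enc.config.seed,
            },
        }

    for name, enc in model.encoders.items():
        _dump(f"encoder_{name}", enc)
    _dump("fusion", model.fusion)
    with open(out / "model.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_model(model_dir: str | Path) -> MultimodalModel:
    d = Path(model_dir)
    with open(d / "model.yaml") as fh:
        meta = yaml.safe_load(fh)
    classes = tuple(meta["classes"])

    def _load(name: str) -> EncoderModel:
        info = meta["networks"][name]
        data = np.load(d / f"{name}.npz")
        n_layers = len(info["layer_sizes"]) - 1
        net = MLP(
            list(info["layer_sizes"]),
            [data[f"W{i}"] for i in range(n_layers)],
            [data[f"b{i}"] for i in range(n_layers)],
        )
        cfg = EncoderConfig(hidden_sizes=tuple(info["config"]["hidden_sizes"]), **{
            k: info["config"][k]
            for k in ("epochs", "batch_size", "learning_rate", "beta_1", "beta_2", "seed")
        })
        return EncoderModel(net, classes, tuple(info["feature_ids"]), info["modality"], cfg)

    order = tuple(meta["modality_order"])
    encoders = {name: _load(f"encoder_{name}") for name in order}
    return MultimodalModel(encoders, _load("fusion"), classes, order)
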
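"""Encoder/classifier contracts, label-smoothed source training, and
bundle serialization.

All models decompose into a feature encoder mapping inputs to R^d and a
linear classifier mapping R^d to K logits. Any object honoring
:class:`EncoderContract` (MLP, small CNN, or an injected external
backbone) runs through the full pipeline unchanged; only d and K must
agree across models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from . import nn
from .data import DomainDataset
from .errors import (
    InvalidInputError,
    InvalidLabelError,
    InvalidParameterError,
    NumericError,
    ShapeError,
)


@runtime_checkable
class EncoderContract(Protocol):
    """Maps a batch of inputs to (N, d) features, with backprop support."""

    out_dim: int

    def forward(self, x: np.ndarray) -> np.ndarray: ...
    def backward(self, grad_out: np.ndarray) -> np.ndarray: ...
    def params(self) -> list[nn.Param]: ...


class MLPEncoder(nn.Sequential):
    """Two-layer perceptron encoder with a normalized feature bottleneck.

    The closing batch-statistics normalization keeps features centered
    and scaled, which the cosine-distance pseudo-labeling and the
    entropy objectives downstream rely on (the deep backbones this
    stands in for carry batch norm throughout).
    """

    def __init__(self, d_in: int, d_out: int, hidden: int, rng: np.random.Generator):
        super().__init__(
            nn.Linear(d_in, hidden, rng),
            nn.ReLU(),
            nn.Linear(hidden, d_out, rng),
            nn.BatchNorm1d(d_out),
        )
        self.in_dim = d_in
        self.out_dim = d_out
        self.hidden = hidden


class SmallCNNEncoder(nn.Sequential):
    """Tiny convolutional encoder for square RGB images.

    Accepts (N, side, side, 3) uint8/float arrays; internally rescales to
    [0, 1] and NCHW. Two 3x3 conv blocks with average pooling, global
    average pool, and a linear projection to d.
    """

    def __init__(self, side: int, d_out: int, rng: np.random.Generator, channels: tuple[int, int] = (8, 16)):
        c1, c2 = channels
        super().__init__(
            nn.Conv2d(3, c1, 3, rng),
            nn.ReLU(),
            nn.AvgPool2d(2),
            nn.Conv2d(c1, c2, 3, rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
            nn.Linear(c2, d_out, rng),
            nn.BatchNorm1d(d_out),
        )
        self.side = side
        self.out_dim = d_out
        self.channels = (c1, c2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != 3:
            raise ShapeError(f"expected (N, H, W, 3) images, got {x.shape}")
        x = x.astype(np.float64) / 255.0
        return super().forward(x.transpose(0, 3, 1, 2))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return super().backward(grad_out)  # image-space grad unused downstream


class LinearClassifier(nn.Linear):
    """R^d -> R^K logits; ``frozen`` disables its use in optimizers."""

    def __init__(self, d: int, k: int, rng: np.random.Generator):
        super().__init__(d, k, rng)
        self.in_dim = d
        self.n_classes = k
        self.frozen = False


def build_encoder(
    arch: str,
    in_shape,
    d: int,
    rng: np.random.Generator,
    hidden: int | None = None,
    channels: tuple[int, int] | None = None,
):
    """Encoder factory used by the CLI. ``in_shape`` is d_in or image side."""
    if arch == "mlp":
        return MLPEncoder(int(in_shape), d, hidden=hidden or max(2 * d, 32), rng=rng)
    if arch == "smallcnn":
        return SmallCNNEncoder(int(in_shape), d, rng, channels=channels or (8, 16))
    if arch == "resnet50":
        raise InvalidParameterError(
            "arch 'resnet50' requires torch/torchvision, which are not installed; "
            "inject a torch-backed EncoderContract object via the library API instead"
        )
    raise InvalidParameterError(f"unknown arch {arch!r}")


def _encoder_hyperparams(encoder) -> dict:
    if isinstance(encoder, SmallCNNEncoder):
        return {"hidden": 0, "channels": list(encoder.channels)}
    if isinstance(encoder, MLPEncoder):
        return {"hidden": encoder.hidden, "channels": None}
    return {"hidden": 0, "channels": None}


def smooth_labels(y: int, k: int, alpha: float) -> np.ndarray:
    """Smoothed one-hot target: (1-alpha) on class y plus alpha/K everywhere."""
    if not 0 <= alpha < 1:
        raise InvalidParameterError(f"alpha must be in [0, 1), got {alpha}")
    if not 0 <= y < k:
        raise InvalidLabelError(f"label {y} outside [0, {k})")
    q = np.full(k, alpha / k)
    q[y] += 1.0 - alpha
    return q


def smooth_labels_batch(y: np.ndarray, k: int, alpha: float) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.min(initial=0) < 0 or y.max(initial=0) >= k:
        raise InvalidLabelError(f"labels outside [0, {k})")
    q = np.full((len(y), k), alpha / k)
    q[np.arange(len(y)), y] += 1.0 - alpha
    return q


def source_ce_loss(logits: np.ndarray, target: np.ndarray) -> float:
    """Cross-entropy of softmax(logits) against a (smoothed) label vector."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise NumericError("non-finite logits")
    logp = nn.log_softmax(logits, axis=-1)
    return float(-(np.asarray(target) * logp).sum(axis=-1).mean())


@dataclass
class TrainConfig:
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 5e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    alpha: float = 0.1

    def __post_init__(self):
        if self.epochs < 1:
            raise InvalidParameterError("epochs must be >= 1")
        if not 0 <= self.alpha < 1:
            raise InvalidParameterError("alpha must be in [0, 1)")


@dataclass
class SourceModelBundle:
    """A frozen source model: encoder f_i plus classifier p_i."""

    encoder: EncoderContract
    classifier: LinearClassifier
    domain_name: str
    d: int
    k: int
    arch: str = "mlp"
    in_shape: int = 0

    def features(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(x)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.classifier.forward(self.features(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(x))

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        enc_state = nn.get_state(self.encoder)
        clf_state = nn.get_state(self.classifier)
        arrays = {f"enc_{i}": a for i, a in enumerate(enc_state)}
        arrays.update({f"clf_{i}": a for i, a in enumerate(clf_state)})
        np.savez(out_dir / "params.npz", **arrays)
        meta = {
            "domain_name": self.domain_name,
            "d": self.d,
            "k": self.k,
            "arch": self.arch,
            "in_shape": self.in_shape,
            "n_enc_params": len(enc_state),
            "n_clf_params": len(clf_state),
            **_encoder_hyperparams(self.encoder),
        }
        (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "SourceModelBundle":
        bundle_dir = Path(bundle_dir)
        meta_path = bundle_dir / "meta.json"
        if not meta_path.exists():
            raise InvalidInputError(f"no bundle at {bundle_dir} (meta.json missing)")
        meta = json.loads(meta_path.read_text())
        rng = np.random.default_rng(0)  # values overwritten below
        encoder = build_encoder(
            meta["arch"], meta["in_shape"], meta["d"], rng,
            hidden=meta.get("hidden") or None,
            channels=tuple(meta["channels"]) if meta.get("channels") else None,
        )
        classifier = LinearClassifier(meta["d"], meta["k"], rng)
        with np.load(bundle_dir / "params.npz") as blob:
            nn.set_state(encoder, [blob[f"enc_{i}"] for i in range(meta["n_enc_params"])])
            nn.set_state(classifier, [blob[f"clf_{i}"] for i in range(meta["n_clf_params"])])
        classifier.frozen = True
        return cls(
            encoder=encoder,
            classifier=classifier,
            domain_name=meta["domain_name"],
            d=meta["d"],
            k=meta["k"],
            arch=meta["arch"],
            in_shape=meta["in_shape"],
        )


@dataclass
class TargetModel:
    """Trainable encoder f_t classified through frozen fused source heads."""

    encoder: EncoderContract
    fused_W: np.ndarray = field(repr=False, default=None)  # (d, K)
    fused_b: np.ndarray = field(repr=False, default=None)  # (K,)
    d: int = 0
    k: int = 0

    def features(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(x)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.features(x) @ self.fused_W + self.fused_b

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(x))

    def save(self, out_dir: str | Path, arch: str = "mlp", in_shape: int = 0) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        enc_state = nn.get_state(self.encoder)
        arrays = {f"enc_{i}": a for i, a in enumerate(enc_state)}
        arrays["fused_W"] = self.fused_W
        arrays["fused_b"] = self.fused_b
        np.savez(out_dir / "params.npz", **arrays)
        meta = {
            "domain_name": "target",
            "d": self.d,
            "k": self.k,
            "arch": arch,
            "in_shape": in_shape,
            "n_enc_params": len(enc_state),
            "kind": "target",
            **_encoder_hyperparams(self.encoder),
        }
        (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "TargetModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "meta.json").read_text())
        rng = np.random.default_rng(0)
        encoder = build_encoder(
            meta["arch"], meta["in_shape"], meta["d"], rng,
            hidden=meta.get("hidden") or None,
            channels=tuple(meta["channels"]) if meta.get("channels") else None,
        )
        with np.load(model_dir / "params.npz") as blob:
            nn.set_state(encoder, [blob[f"enc_{i}"] for i in range(meta["n_enc_params"])])
            fused_W = blob["fused_W"].copy()
            fused_b = blob["fused_b"].copy()
        return cls(encoder=encoder, fused_W=fused_W, fused_b=fused_b, d=meta["d"], k=meta["k"])


def train_source_suite(
    sources: list[DomainDataset],
    d: int,
    seed: int,
    cfg: TrainConfig | None = None,
    k: int = 2,
) -> list["SourceModelBundle"]:
    """Train one bundle per source domain from a SHARED initialization.

    All encoders (and classifier heads) start from identical parameters,
    mirroring the shared pretrained starting point of the deep backbones
    this stands in for. Without it the per-source feature spaces end up
    mutually incompatible and fusing classifier heads across them is
    meaningless.
    """
    cfg = cfg or TrainConfig()
    bundles = []
    for i, src in enumerate(sources):
        rng = np.random.default_rng(seed)  # same init for every source
        if src.kind == "image":
            encoder: EncoderContract = SmallCNNEncoder(src.X.shape[1], d, rng)
        else:
            encoder = MLPEncoder(src.X.shape[1], d, hidden=max(2 * d, 32), rng=rng)
        classifier = LinearClassifier(d, k, rng)
        cfg_i = TrainConfig(
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            momentum=cfg.momentum,
            weight_decay=cfg.weight_decay,
            alpha=cfg.alpha,
            seed=seed * 100 + i,
        )
        bundles.append(train_source(src, cfg_i, encoder, classifier=classifier))
    return bundles


def train_source(
    data: DomainDataset,
    cfg: TrainConfig,
    encoder: EncoderContract,
    classifier: LinearClassifier | None = None,
    k: int | None = None,
) -> SourceModelBundle:
    """Train one source model with label-smoothed cross-entropy.

    Deterministic given ``cfg.seed`` (shuffling only; parameter init is
    the caller's, typically from the same seed).
    """
    y = data.require_labels()
    if k is None:
        k = int(y.max()) + 1 if classifier is None else classifier.n_classes
    rng = np.random.default_rng(cfg.seed)
    if classifier is None:
        classifier = LinearClassifier(encoder.out_dim, k, rng)
    targets = smooth_labels_batch(y, k, cfg.alpha)
    params = encoder.params() + classifier.params()
    opt = nn.SGD(params, lr=cfg.learning_rate, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    n = len(data)
    bs = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, qb = data.X[idx], targets[idx]
            feats = encoder.forward(xb)
            logits = classifier.forward(feats)
            probs = nn.softmax(logits)
            grad = (probs - qb) / len(idx)
            opt.zero_grad()
            encoder.backward(classifier.backward(grad))
            opt.step()
    classifier.frozen = True
    in_shape = getattr(encoder, "in_dim", getattr(encoder, "side", 0))
    arch = "smallcnn" if isinstance(encoder, SmallCNNEncoder) else "mlp"
    return SourceModelBundle(
        encoder=encoder,
        classifier=classifier,
        domain_name=data.domain,
        d=encoder.out_dim,
        k=k,
        arch=arch,
        in_shape=in_shape,
    )
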
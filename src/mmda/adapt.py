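"""Target-model adaptation loop.

Optimizes a trainable target encoder against frozen, importance-weighted
source classifier heads. Warm-up epochs use the information-maximization
(IM) objective alone with uniform weights; afterwards each epoch (1)
extracts features, (2) refreshes the source weights mu, (3) refreshes
pseudo labels, and (4) runs minibatch SGD on IM + weighted pseudo-label
cross-entropy. Source parameters are never updated.

Variants: ``MMDA`` uses the learned mu everywhere; ``ACDA`` forces
uniform mu in classifier fusion only; ``APDA`` forces uniform mu in
pseudo-labeling only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from . import nn, pseudo, weights
from .data import DomainDataset
from .errors import (
    IncompatibilityError,
    InvalidDistributionError,
    InvalidParameterError,
    ShapeError,
)
from .models import (
    EncoderContract,
    MLPEncoder,
    SmallCNNEncoder,
    SourceModelBundle,
    TargetModel,
)

VARIANTS = ("MMDA", "ACDA", "APDA")


@dataclass
class IMLossParams:
    beta: float = 0.3

    def __post_init__(self):
        if self.beta < 0:
            raise InvalidParameterError(f"beta must be >= 0, got {self.beta}")


@dataclass
class AdaptationConfig:
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-2
    momentum: float = 0.9
    weight_decay: float = 1e-4
    beta: float = 0.3
    gamma: float = 0.3
    warmup_epochs: int = 5
    seed: int = 0
    variant: str = "MMDA"
    wd_steps: int = 50
    wd_lr: float = 1e-2
    pseudo_rounds: int = 2
    augment: bool = True  # image tier only
    init: str = "source"  # "source": warm-start f_t from bundles[0]; "random"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidParameterError(f"variant must be one of {VARIANTS}")
        if self.init not in ("source", "random"):
            raise InvalidParameterError("init must be 'source' or 'random'")
        if self.warmup_epochs >= self.epochs:
            raise InvalidParameterError("warmup_epochs must be < epochs")
        if self.gamma < 0 or self.beta < 0:
            raise InvalidParameterError("beta and gamma must be >= 0")


@dataclass
class LossReport:
    epoch: int
    l_ce_entropy: float
    l_div: float
    l_im: float
    l_pseudo: float
    l_overall: float
    l_wd: float
    mu_learned: np.ndarray = field(default=None)
    mu_fusion: np.ndarray = field(default=None)
    mu_pseudo: np.ndarray = field(default=None)


@dataclass
class FusedClassifier:
    """mu-weighted sum of frozen linear source heads, fused at logit level."""

    bundles: list[SourceModelBundle]
    mu: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        if len(self.mu) != len(self.bundles):
            raise ShapeError(f"{len(self.mu)} weights for {len(self.bundles)} bundles")
        self.W = sum(m * b.classifier.W.value for m, b in zip(self.mu, self.bundles))
        self.b = sum(m * b.classifier.b.value for m, b in zip(self.mu, self.bundles))


def fused_logits(feats: np.ndarray, fused: FusedClassifier) -> np.ndarray:
    feats = np.asarray(feats, dtype=np.float64)
    if feats.ndim != 2 or feats.shape[1] != fused.W.shape[0]:
        raise ShapeError(f"features {feats.shape} incompatible with fused head {fused.W.shape}")
    return feats @ fused.W + fused.b


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if np.any(probs < 0):
        raise InvalidDistributionError("negative probabilities")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise InvalidDistributionError("probability rows must sum to 1")
    return probs


def im_loss(probs: np.ndarray, params: IMLossParams) -> tuple[float, float, float]:
    """Certainty + diversity objective.

    l_ce is the mean per-sample output entropy, l_div the negative
    entropy of the batch-mean output distribution; l_im = l_ce + beta*l_div
    (0 log 0 := 0).
    """
    probs = _check_probs(probs)
    l_ce = float(-xlogy(probs, probs).sum(axis=1).mean())
    p_bar = probs.mean(axis=0)
    l_div = float(xlogy(p_bar, p_bar).sum())
    return l_ce, l_div, l_ce + params.beta * l_div


def pseudo_ce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of output probabilities against hard pseudo labels."""
    probs = _check_probs(probs)
    idx = np.arange(len(labels))
    return float(-np.log(np.clip(probs[idx, np.asarray(labels, dtype=int)], 1e-300, None)).mean())


def overall_loss(
    probs: np.ndarray,
    pseudo_state: pseudo.PseudoLabelState,
    params: IMLossParams,
    gamma: float,
) -> float:
    """IM loss plus gamma times pseudo-label cross-entropy."""
    _, _, l_im = im_loss(probs, params)
    return l_im + gamma * pseudo_ce_loss(probs, pseudo_state.labels)


def _im_grad(probs: np.ndarray, beta: float) -> np.ndarray:
    """Gradient of the IM loss w.r.t. the logits, for one minibatch."""
    n = len(probs)
    logp = np.log(np.clip(probs, 1e-300, None))
    ent = -(probs * logp).sum(axis=1)
    g_ce = -(probs * (logp + ent[:, None])) / n
    p_bar = probs.mean(axis=0)
    log_pbar = np.log(np.clip(p_bar, 1e-300, None))
    inner = (probs * log_pbar).sum(axis=1)
    g_div = probs * (log_pbar[None, :] - inner[:, None]) / n
    return g_ce + beta * g_div


def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random flips and quarter-turn rotations for square image batches."""
    out = xb.copy()
    for i in range(len(out)):
        if rng.random() < 0.5:
            out[i] = out[i][:, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i][::-1, :]
        turns = int(rng.integers(0, 4))
        if turns:
            out[i] = np.rot90(out[i], turns)
    return out


def _default_encoder(target: DomainDataset, d: int, rng: np.random.Generator) -> EncoderContract:
    if target.kind == "image":
        return SmallCNNEncoder(target.X.shape[1], d, rng)
    return MLPEncoder(target.X.shape[1], d, hidden=max(2 * d, 32), rng=rng)


def _warm_start(encoder: EncoderContract, bundle: SourceModelBundle) -> None:
    # desk-scale analogue of a pretrained init: copy one source encoder's
    # parameters so the target model starts with meaningful features
    # (IM training from a random encoder collapses to a single class)
    nn.set_state(encoder, nn.get_state(bundle.encoder))


def adapt(
    bundles: list[SourceModelBundle],
    target: DomainDataset,
    cfg: AdaptationConfig,
    encoder: EncoderContract | None = None,
) -> tuple[TargetModel, np.ndarray, list[LossReport]]:
    """Run the full adaptation loop; returns (model, final mu, reports)."""
    if not bundles:
        raise IncompatibilityError("need at least one source bundle")
    d, k = bundles[0].d, bundles[0].k
    for b in bundles[1:]:
        if b.d != d or b.k != k:
            raise IncompatibilityError(
                f"bundle {b.domain_name!r} has (d={b.d}, K={b.k}), expected ({d}, {k})"
            )
    n_src = len(bundles)
    rng = np.random.default_rng(cfg.seed)
    if encoder is None:
        encoder = _default_encoder(target, d, rng)
        if cfg.init == "source":
            try:
                _warm_start(encoder, bundles[0])
            except ShapeError:  # architectures differ; keep the random init
                pass
    if encoder.out_dim != d:
        raise IncompatibilityError(f"encoder out_dim {encoder.out_dim} != bundle d {d}")

    x_t = target.X
    n_t = len(target)
    # source encoders/classifiers are frozen: compute their outputs once
    src_feats = [b.features(x_t) for b in bundles]
    src_probs = [
        nn.softmax(b.classifier.forward(f)) for b, f in zip(bundles, src_feats)
    ]
    src_clf_before = [nn.get_state(b.classifier) for b in bundles]

    net = weights.init_weight_net(d, rng)
    uniform = np.full(n_src, 1.0 / n_src)
    mu_learned = uniform.copy()
    im_params = IMLossParams(cfg.beta)
    opt = nn.SGD(encoder.params(), lr=cfg.lr, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    bs = min(cfg.batch_size, n_t)
    augment = cfg.augment and target.kind == "image"

    prev_centroids: np.ndarray | None = None
    reports: list[LossReport] = []
    pseudo_state: pseudo.PseudoLabelState | None = None

    for epoch in range(cfg.epochs):
        ft_feats = encoder.forward(x_t)
        warm = epoch < cfg.warmup_epochs
        if warm:
            mu_learned = uniform.copy()
            mu_fusion = uniform.copy()
            mu_pseudo = uniform.copy()
            pseudo_state = None
            gamma_eff = 0.0
        else:
            tau = weights.distance_profiles(src_feats, ft_feats)
            net = weights.update_weight_net(
                net, tau, src_feats, ft_feats, steps=cfg.wd_steps, lr=cfg.wd_lr
            )
            mu_learned = weights.model_weights(tau, net)
            mu_fusion = uniform.copy() if cfg.variant == "ACDA" else mu_learned.copy()
            mu_pseudo = uniform.copy() if cfg.variant == "APDA" else mu_learned.copy()
            pseudo_state = pseudo.pseudo_label(
                src_probs,
                src_feats,
                ft_feats,
                mu_pseudo,
                rounds=cfg.pseudo_rounds,
                fallback=prev_centroids,
            )
            prev_centroids = pseudo_state.centroids.m
            gamma_eff = cfg.gamma

        fused = FusedClassifier(bundles, mu_fusion)
        order = rng.permutation(n_t)
        for start in range(0, n_t, bs):
            idx = order[start : start + bs]
            xb = x_t[idx]
            if augment:
                xb = _augment_batch(xb, rng)
            feats = encoder.forward(xb)
            probs = nn.softmax(fused_logits(feats, fused))
            grad_logits = _im_grad(probs, cfg.beta)
            if pseudo_state is not None and gamma_eff > 0:
                onehot = np.zeros_like(probs)
                onehot[np.arange(len(idx)), pseudo_state.labels[idx]] = 1.0
                grad_logits = grad_logits + gamma_eff * (probs - onehot) / len(idx)
            opt.zero_grad()
            encoder.backward(grad_logits @ fused.W.T)
            opt.step()

        # full-set report with end-of-epoch parameters
        ft_feats = encoder.forward(x_t)
        probs = nn.softmax(fused_logits(ft_feats, fused))
        l_ce, l_div, l_im = im_loss(probs, im_params)
        l_pseudo = pseudo_ce_loss(probs, pseudo_state.labels) if pseudo_state is not None else 0.0
        l_wd = weights.weight_determination_loss(mu_learned, src_feats, ft_feats)
        reports.append(
            LossReport(
                epoch=epoch,
                l_ce_entropy=l_ce,
                l_div=l_div,
                l_im=l_im,
                l_pseudo=l_pseudo,
                l_overall=l_im + gamma_eff * l_pseudo,
                l_wd=l_wd,
                mu_learned=mu_learned.copy(),
                mu_fusion=mu_fusion.copy(),
                mu_pseudo=mu_pseudo.copy(),
            )
        )

    for b, before in zip(bundles, src_clf_before):
        for p, v in zip(b.classifier.params(), before):
            assert np.array_equal(p.value, v), "source classifier was mutated"

    final_fused = FusedClassifier(bundles, reports[-1].mu_fusion)
    model = TargetModel(encoder=encoder, fused_W=final_fused.W, fused_b=final_fused.b, d=d, k=k)
    return model, mu_learned, reports


def uniform_ensemble_proba(bundles: list[SourceModelBundle], x: np.ndarray) -> np.ndarray:
    """Source-only baseline: average the softmax outputs of all bundles."""
    return np.mean([b.predict_proba(x) for b in bundles], axis=0)
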
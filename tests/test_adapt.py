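import numpy as np
import pytest

from mmda import nn
from mmda.adapt import (
    AdaptationConfig,
    FusedClassifier,
    IMLossParams,
    _im_grad,
    adapt,
    fused_logits,
    im_loss,
    overall_loss,
    pseudo_ce_loss,
    uniform_ensemble_proba,
)
from mmda.errors import (
    IncompatibilityError,
    InvalidDistributionError,
    InvalidParameterError,
)
from mmda.models import MLPEncoder, TrainConfig, train_source_suite
from mmda.pseudo import CentroidSet, PseudoLabelState
from mmda.weights import init_weight_net
from mmda.synthetic import default_feature_benchmark


class TestFusedLogits:
    def test_single_source_identity(self, small_bundles, small_benchmark):
        x = small_benchmark.target.X[:10]
        b = small_bundles[0]
        fused = FusedClassifier([b], np.array([1.0]))
        assert np.allclose(fused_logits(b.features(x), fused), b.logits(x), atol=1e-12)

    def test_cancellation(self, rng):
        feats = rng.normal(size=(6, 4))

        class Stub:
            def __init__(self, W, b):
                self.classifier = type("C", (), {})()
                self.classifier.W = nn.Param(W)
                self.classifier.b = nn.Param(b)

        W = rng.normal(size=(4, 3))
        b = rng.normal(size=3)
        fused = FusedClassifier([Stub(W, b), Stub(-W, -b)], np.array([0.5, 0.5]))
        assert np.allclose(fused_logits(feats, fused), 0.0, atol=1e-12)

    def test_matches_weighted_sum_oracle(self, small_bundles, small_benchmark):
        x = small_benchmark.target.X[:8]
        mu = np.array([0.2, 0.5, 0.3])
        feats = small_bundles[0].features(x)  # any shared-d features
        fused = FusedClassifier(small_bundles, mu)
        expect = sum(
            m * (feats @ b.classifier.W.value + b.classifier.b.value)
            for m, b in zip(mu, small_bundles)
        )
        assert np.allclose(fused_logits(feats, fused), expect, atol=1e-12)


class TestIMLoss:
    def test_uniform_rows(self):
        probs = np.full((10, 4), 0.25)
        l_ce, l_div, l_im = im_loss(probs, IMLossParams(beta=0.3))
        assert l_ce == pytest.approx(np.log(4), abs=1e-12)
        assert l_div == pytest.approx(-np.log(4), abs=1e-12)
        assert l_im == pytest.approx(np.log(4) - 0.3 * np.log(4), abs=1e-12)

    def test_balanced_one_hot(self):
        probs = np.zeros((8, 4))
        probs[np.arange(8), np.arange(8) % 4] = 1.0
        l_ce, l_div, _ = im_loss(probs, IMLossParams())
        assert l_ce == pytest.approx(0.0, abs=1e-12)
        assert l_div == pytest.approx(-np.log(4), abs=1e-12)

    def test_div_kl_identity(self, rng):
        # oracle: sum P log P == KL(P || uniform) - log K
        for _ in range(10):
            probs = rng.dirichlet(np.ones(5), size=20)
            _, l_div, _ = im_loss(probs, IMLossParams())
            p_bar = probs.mean(axis=0)
            kl = float(np.sum(p_bar * np.log(p_bar * 5)))
            assert l_div == pytest.approx(kl - np.log(5), abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            probs = rng.dirichlet(np.ones(3), size=15)
            l_ce, l_div, _ = im_loss(probs, IMLossParams())
            assert 0.0 <= l_ce <= np.log(3) + 1e-12
            assert -np.log(3) - 1e-12 <= l_div <= 0.0

    def test_negative_probs_rejected(self):
        with pytest.raises(InvalidDistributionError):
            im_loss(np.array([[1.2, -0.2]]), IMLossParams())

    def test_zero_log_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        l_ce, l_div, _ = im_loss(probs, IMLossParams())
        assert np.isfinite(l_ce) and np.isfinite(l_div)

    def test_grad_matches_finite_difference(self, rng):
        z = rng.normal(size=(6, 4))
        beta = 0.3

        def f(zv):
            p = nn.softmax(zv)
            l_ce, l_div, l_im = im_loss(p, IMLossParams(beta))
            return l_im

        g = _im_grad(nn.softmax(z), beta)
        eps = 1e-6
        for i in range(6):
            for j in range(4):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                assert (f(zp) - f(zm)) / (2 * eps) == pytest.approx(g[i, j], abs=1e-6)


class TestOverallLoss:
    def _state(self, labels, k, d=3):
        return PseudoLabelState(labels, CentroidSet(np.ones((k, d))))

    def test_gamma_zero_equals_im(self, rng):
        probs = rng.dirichlet(np.ones(4), size=10)
        state = self._state(rng.integers(0, 4, size=10), 4)
        _, _, l_im = im_loss(probs, IMLossParams(0.3))
        assert overall_loss(probs, state, IMLossParams(0.3), 0.0) == pytest.approx(l_im)

    def test_perfect_predictions_zero_ce(self):
        probs = np.zeros((6, 3))
        labels = np.array([0, 1, 2, 0, 1, 2])
        probs[np.arange(6), labels] = 1.0
        assert pseudo_ce_loss(probs, labels) == pytest.approx(0.0, abs=1e-9)

    def test_matches_term_oracle(self, rng):
        probs = rng.dirichlet(np.ones(3), size=12)
        labels = rng.integers(0, 3, size=12)
        state = self._state(labels, 3)
        got = overall_loss(probs, state, IMLossParams(0.4), 0.7)
        ce = -np.mean([np.log(probs[t, labels[t]]) for t in range(12)])
        _, _, l_im = im_loss(probs, IMLossParams(0.4))
        assert got == pytest.approx(l_im + 0.7 * ce, abs=1e-10)


class TestAdaptEngine:
    def test_source_classifiers_untouched(self, small_bundles, small_benchmark, quick_adapt_cfg):
        before = [nn.get_state(b.classifier) for b in small_bundles]
        adapt(small_bundles, small_benchmark.target, quick_adapt_cfg)
        after = [nn.get_state(b.classifier) for b in small_bundles]
        for b1, b2 in zip(before, after):
            for p1, p2 in zip(b1, b2):
                assert np.array_equal(p1, p2)

    def test_deterministic(self, small_bundles, small_benchmark, quick_adapt_cfg):
        _, mu1, rep1 = adapt(small_bundles, small_benchmark.target, quick_adapt_cfg)
        _, mu2, rep2 = adapt(small_bundles, small_benchmark.target, quick_adapt_cfg)
        assert np.array_equal(mu1, mu2)
        for r1, r2 in zip(rep1, rep2):
            assert r1.l_overall == r2.l_overall
            assert r1.l_wd == r2.l_wd

    def test_loss_report_identities(self, small_bundles, small_benchmark, quick_adapt_cfg):
        _, _, reports = adapt(small_bundles, small_benchmark.target, quick_adapt_cfg)
        cfg = quick_adapt_cfg
        for r in reports:
            assert r.l_im == pytest.approx(r.l_ce_entropy + cfg.beta * r.l_div, abs=1e-12)
            gamma = 0.0 if r.epoch < cfg.warmup_epochs else cfg.gamma
            assert r.l_overall == pytest.approx(r.l_im + gamma * r.l_pseudo, abs=1e-12)
            assert -np.log(2) - 1e-9 <= r.l_div <= 1e-9
            assert -1e-9 <= r.l_ce_entropy <= np.log(2) + 1e-9

    def test_warmup_uses_uniform_mu(self, small_bundles, small_benchmark, quick_adapt_cfg):
        _, _, reports = adapt(small_bundles, small_benchmark.target, quick_adapt_cfg)
        for r in reports[: quick_adapt_cfg.warmup_epochs]:
            assert np.allclose(r.mu_fusion, 1 / 3)
            assert np.allclose(r.mu_pseudo, 1 / 3)

    @pytest.mark.parametrize("variant,uniform_field,learned_field", [
        ("ACDA", "mu_fusion", "mu_pseudo"),
        ("APDA", "mu_pseudo", "mu_fusion"),
    ])
    def test_variant_wiring(self, small_bundles, small_benchmark, variant,
                            uniform_field, learned_field):
        cfg = AdaptationConfig(epochs=6, warmup_epochs=2, seed=0, variant=variant)
        _, _, reports = adapt(small_bundles, small_benchmark.target, cfg)
        post = [r for r in reports if r.epoch >= cfg.warmup_epochs]
        for r in post:
            assert np.allclose(getattr(r, uniform_field), 1 / 3)
            assert np.array_equal(getattr(r, learned_field), r.mu_learned)
        # the learned mu must actually depart from uniform somewhere
        assert any(not np.allclose(r.mu_learned, 1 / 3) for r in post)

    def test_incompatible_bundles_rejected(self, small_benchmark):
        b1 = train_source_suite([small_benchmark.sources[0]], d=8, seed=0,
                                cfg=TrainConfig(epochs=1))[0]
        b2 = train_source_suite([small_benchmark.sources[1]], d=16, seed=0,
                                cfg=TrainConfig(epochs=1))[0]
        with pytest.raises(IncompatibilityError):
            adapt([b1, b2], small_benchmark.target, AdaptationConfig(epochs=2, warmup_epochs=1))

    def test_no_bundles_rejected(self, small_benchmark):
        with pytest.raises(IncompatibilityError):
            adapt([], small_benchmark.target, AdaptationConfig(epochs=2, warmup_epochs=1))

    def test_bad_config(self):
        with pytest.raises(InvalidParameterError):
            AdaptationConfig(epochs=5, warmup_epochs=5)
        with pytest.raises(InvalidParameterError):
            AdaptationConfig(variant="XXX")

    def test_single_source_warmup_only_reduces_to_im_loop(self, small_benchmark):
        """n=1, warmup==epochs-ish: engine must match a hand-rolled IM loop."""
        bundles = train_source_suite([small_benchmark.sources[0]], d=16, seed=0,
                                     cfg=TrainConfig(epochs=5))
        target = small_benchmark.target
        cfg = AdaptationConfig(epochs=6, warmup_epochs=5, gamma=0.0, seed=3)
        model, mu, reports = adapt(bundles, target, cfg)
        assert mu == pytest.approx([1.0])

        # hand-rolled: same seeding scheme, IM-only minibatch SGD
        rng = np.random.default_rng(3)
        enc = MLPEncoder(16, 16, hidden=32, rng=rng)
        nn.set_state(enc, nn.get_state(bundles[0].encoder))
        init_weight_net(16, rng)  # engine draws the weight net from the same stream
        W = bundles[0].classifier.W.value
        b = bundles[0].classifier.b.value
        opt = nn.SGD(enc.params(), lr=cfg.lr, momentum=cfg.momentum,
                     weight_decay=cfg.weight_decay)
        n = len(target)
        manual = []
        for epoch in range(cfg.epochs):
            enc.forward(target.X)
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                feats = enc.forward(target.X[idx])
                probs = nn.softmax(feats @ W + b)
                opt.zero_grad()
                enc.backward(_im_grad(probs, cfg.beta) @ W.T)
                opt.step()
            probs = nn.softmax(enc.forward(target.X) @ W + b)
            _, _, l_im = im_loss(probs, IMLossParams(cfg.beta))
            manual.append(l_im)
        for r, l in zip(reports, manual):
            assert r.l_im == pytest.approx(l, abs=1e-8)


def test_adaptation_beats_uniform_ensemble_smoke(small_bundles, small_benchmark):
    """Reduced-n version of the headline property (full scale in acceptance)."""
    truth = small_benchmark.target_labels
    base = (uniform_ensemble_proba(small_bundles, small_benchmark.target.X).argmax(1)
            == truth).mean()
    model, mu, _ = adapt(small_bundles, small_benchmark.target,
                         AdaptationConfig(epochs=15, warmup_epochs=3, seed=0))
    acc = (model.predict_proba(small_benchmark.target.X).argmax(1) == truth).mean()
    assert acc > base


def test_matched_source_gets_top_mu_smoke():
    bench = default_feature_benchmark(seed=1, n_per_class=60, matched_source=True)
    bundles = train_source_suite(bench.sources, d=16, seed=1, cfg=TrainConfig(epochs=15))
    _, mu, _ = adapt(bundles, bench.target, AdaptationConfig(epochs=15, warmup_epochs=3, seed=1))
    assert int(np.argmax(mu)) == 0
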
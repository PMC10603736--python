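"""Adaptation objectives: MK-MMD estimator, GRL, and the three losses."""

import math

import numpy as np
import pytest

from aardapt import models as md
from aardapt import uda
from aardapt.nn import Adam, Tensor
from aardapt.nn import functional as F
from aardapt.training import _make_bundle


def mmd_oracle(A, B, bandwidths, estimator="unbiased"):
    """Independent O(n^2) double-loop computation of the multi-kernel
    squared-MMD estimator (the reference the fast path must match)."""
    m, n = len(A), len(B)
    total = 0.0
    for bw in bandwidths:
        def k(x, y):
            return math.exp(-float(np.sum((x - y) ** 2)) / bw)

        s_aa = sum(k(A[i], A[j]) for i in range(m) for j in range(m) if i != j)
        s_bb = sum(k(B[i], B[j]) for i in range(n) for j in range(n) if i != j)
        if estimator == "unbiased":
            term_a = s_aa / (m * (m - 1))
            term_b = s_bb / (n * (n - 1))
            if m == n:
                cross = 2.0 * sum(k(A[i], B[j]) for i in range(m)
                                  for j in range(n) if i != j) / (m * (m - 1))
            else:
                cross = 2.0 * sum(k(A[i], B[j]) for i in range(m)
                                  for j in range(n)) / (m * n)
        else:
            term_a = (s_aa + m) / (m * m)          # diagonal k = 1
            term_b = (s_bb + n) / (n * n)
            cross = 2.0 * sum(k(A[i], B[j]) for i in range(m)
                              for j in range(n)) / (m * n)
        total += term_a + term_b - cross
    return total


class TestMkMmd:
    def test_identical_point_sets_give_exact_zero(self, rng):
        A = rng.standard_normal((16, 8))
        assert uda.mk_mmd(A, A.copy()).item() == 0.0

    @pytest.mark.parametrize("m,n,d", [(8, 8, 4), (12, 7, 3), (5, 20, 16)])
    def test_matches_double_loop_oracle(self, m, n, d, rng):
        A = rng.standard_normal((m, d))
        B = rng.standard_normal((n, d)) + 0.5
        bank = uda.KernelBank.from_median_heuristic(np.concatenate([A, B]))
        for estimator in ("unbiased", "biased"):
            fast = uda.mk_mmd(A, B, kernels=bank, estimator=estimator).item()
            slow = mmd_oracle(A, B, bank.bandwidths, estimator)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_symmetry(self, rng):
        A = rng.standard_normal((10, 5))
        B = rng.standard_normal((14, 5))
        bank = uda.KernelBank(bandwidths=np.array([0.5, 2.0]))
        assert uda.mk_mmd(A, B, bank).item() == uda.mk_mmd(B, A, bank).item()

    def test_null_distribution_centred_near_zero(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(100):
            A = rng.standard_normal((32, 4))
            B = rng.standard_normal((32, 4))
            vals.append(uda.mk_mmd(A, B).item())
        se = np.std(vals) / 10.0
        assert abs(np.mean(vals)) < 2 * se + 1e-3

    def test_separated_distributions_strictly_positive(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            A = rng.standard_normal((24, 3))
            B = rng.standard_normal((24, 3)) + 3.0
            assert uda.mk_mmd(A, B).item() > 0

    def test_biased_estimator_nonnegative(self, rng):
        for _ in range(20):
            A = rng.standard_normal((10, 2))
            B = rng.standard_normal((12, 2))
            assert uda.mk_mmd(A, B, estimator="biased").item() >= 0

    def test_small_batch_rejected_for_unbiased(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            uda.mk_mmd(rng.standard_normal((1, 3)), rng.standard_normal((5, 3)))

    def test_differentiable_and_gradient_checks(self, rng):
        from tests.test_nn import numeric_grad

        A0 = rng.standard_normal((5, 3))
        B = rng.standard_normal((6, 3)) + 1.0
        bank = uda.KernelBank(bandwidths=np.array([1.0, 4.0]))
        t = Tensor(A0.copy(), requires_grad=True)
        uda.mk_mmd(t, Tensor(B), bank).backward()
        num = numeric_grad(
            lambda A: uda.mk_mmd(Tensor(A), Tensor(B), bank).item(), A0.copy())
        np.testing.assert_allclose(t.grad, num, atol=1e-6)


class TestGradientReversal:
    def test_forward_is_identity(self):
        x = Tensor(np.array([1.0, 2.0]))
        np.testing.assert_array_equal(uda.gradient_reversal(x).data, [1.0, 2.0])

    def test_backward_flips_sign(self):
        x = Tensor(np.array([3.0, -1.0]), requires_grad=True)
        out = uda.gradient_reversal(x, beta=1.0)
        out.backward(np.array([0.5, -1.0]))
        np.testing.assert_array_equal(x.grad, [-0.5, 1.0])

    @pytest.mark.parametrize("beta", [1.0, 0.5, 2.0])
    def test_matches_negated_finite_difference(self, beta, rng):
        from tests.test_nn import numeric_grad

        w = rng.standard_normal((3, 3))
        x0 = rng.standard_normal(3)

        def with_grl(x):
            t = x if isinstance(x, Tensor) else Tensor(x)
            return ((uda.gradient_reversal(t, beta) @ Tensor(w)) ** 2).sum()

        def without(x):
            t = x if isinstance(x, Tensor) else Tensor(x)
            return ((t @ Tensor(w)) ** 2).sum()

        t = Tensor(x0.copy(), requires_grad=True)
        with_grl(t).backward()
        plain = numeric_grad(lambda x: without(Tensor(x)).item(), x0.copy())
        np.testing.assert_allclose(t.grad, -beta * plain, atol=1e-5)

    def test_double_application_restores_gradient(self, rng):
        x0 = rng.standard_normal(4)
        t1 = Tensor(x0.copy(), requires_grad=True)
        (uda.gradient_reversal(uda.gradient_reversal(t1)) ** 2).sum().backward()
        t2 = Tensor(x0.copy(), requires_grad=True)
        (t2 ** 2).sum().backward()
        np.testing.assert_allclose(t1.grad, t2.grad, atol=1e-12)


@pytest.fixture()
def toy_batches(rng):
    xs = rng.standard_normal((8, 6, 32)).astype(np.float32)
    ys = rng.integers(0, 3, 8)
    xt = rng.standard_normal((8, 6, 32)).astype(np.float32) + 0.3
    return uda.SourceBatch(xs, ys), uda.TargetBatch(xt)


def toy_bundle(method, seed=0):
    return _make_bundle(method, md.ExtractorConfig(),
                        md.ClassifierConfig(n_classes=3), seed=seed,
                        window_length=32)


class TestDanLoss:
    def test_lambda_zero_equals_source_cross_entropy(self, toy_batches):
        src, tgt = toy_batches
        bundle = toy_bundle("dan").eval()
        loss, comps = uda.dan_loss(bundle, src, tgt, lam=0.0)
        feats = bundle.extractor(Tensor(src.xs))
        ce = md.cross_entropy(bundle.classifier(feats), src.ys)
        assert loss.item() == ce.item()
        assert comps["adapt"] == 0.0

    def test_target_equal_to_source_zeroes_adaptation_term(self, toy_batches):
        src, _ = toy_batches
        bundle = toy_bundle("dan").eval()
        loss, comps = uda.dan_loss(bundle, src, uda.TargetBatch(src.xs.copy()),
                                   lam=1.0)
        assert comps["adapt"] == 0.0
        assert loss.item() == comps["ce"]

    def test_recomposes_from_independent_layer_mmds(self, toy_batches):
        src, tgt = toy_batches
        bundle = toy_bundle("dan").eval()
        bank = uda.KernelBank(bandwidths=np.array([1.0, 10.0, 100.0]))
        lam = 0.7
        loss, comps = uda.dan_loss(bundle, src, tgt, kernels=bank, lam=lam)
        # recompute each layer's activation and its MMD independently
        fs = bundle.extractor(Tensor(src.xs))
        ft = bundle.extractor(Tensor(tgt.xt))
        logit_s, hid_s = bundle.classifier.forward_with_hidden(fs)
        logit_t, hid_t = bundle.classifier.forward_with_hidden(ft)
        mmds = [uda.mk_mmd(a.data.astype(np.float64), b.data.astype(np.float64),
                           bank).item()
                for a, b in zip(hid_s + [logit_s], hid_t + [logit_t])]
        expected = comps["ce"] + lam * sum(mmds)
        assert loss.item() == pytest.approx(expected, abs=1e-6)

    def test_head_presence_rejected(self, toy_batches):
        src, tgt = toy_batches
        with pytest.raises(ValueError, match="no method head"):
            uda.dan_loss(toy_bundle("dann"), src, tgt)

    def test_mismatched_window_shapes_rejected(self, toy_batches, rng):
        src, _ = toy_batches
        bad = uda.TargetBatch(rng.standard_normal((4, 6, 64)).astype(np.float32))
        with pytest.raises(ValueError, match="mismatched"):
            uda.dan_loss(toy_bundle("dan"), src, bad)


class TestDannLoss:
    def test_zero_logit_head_gives_two_ln2_adversarial_part(self, toy_batches):
        src, tgt = toy_batches
        bundle = toy_bundle("dann").eval()
        bundle.method_head.out.weight.data[...] = 0.0
        bundle.method_head.out.bias.data[...] = 0.0
        loss, comps = uda.dann_loss(bundle, src, tgt, lam=1.0)
        assert comps["adapt"] == pytest.approx(2 * np.log(2), abs=1e-6)
        assert loss.item() == pytest.approx(comps["ce"] + 2 * np.log(2), abs=1e-6)

    def test_lambda_zero_reduction(self, toy_batches):
        src, tgt = toy_batches
        bundle = toy_bundle("dann").eval()
        loss, comps = uda.dann_loss(bundle, src, tgt, lam=0.0)
        assert comps["adapt"] == 0.0
        feats = bundle.extractor(Tensor(src.xs))
        assert loss.item() == md.cross_entropy(bundle.classifier(feats),
                                               src.ys).item()

    def test_grl_pushes_extractor_against_domain_head(self, toy_batches):
        """The extractor's gradient through the adversarial term has the
        opposite sign of the same gradient with the reversal removed."""
        src, tgt = toy_batches
        bundle = toy_bundle("dann").eval()
        feats = bundle.extractor(Tensor(src.xs))
        g = bundle.method_head
        # gradient of BCE w.r.t. features with and without reversal
        f1 = Tensor(feats.data.copy(), requires_grad=True)
        F.binary_cross_entropy_with_logits(
            g(uda.gradient_reversal(f1)), np.zeros(len(src.xs))).backward()
        f2 = Tensor(feats.data.copy(), requires_grad=True)
        F.binary_cross_entropy_with_logits(
            g(f2), np.zeros(len(src.xs))).backward()
        np.testing.assert_allclose(f1.grad, -f2.grad, atol=1e-6)

    def test_missing_head_rejected(self, toy_batches):
        src, tgt = toy_batches
        with pytest.raises(ValueError, match="domain-classifier"):
            uda.dann_loss(toy_bundle("dan"), src, tgt)


class TestDecoderAndDrcn:
    def test_decoder_shape_contract(self, rng):
        dec = uda.build_decoder(md.ExtractorConfig(), window_length=200, seed=0)
        dec.eval()
        z = Tensor(rng.standard_normal((4, 128)).astype(np.float32))
        out = dec(z)
        assert out.shape == (4, 6, 200)
        assert np.all(np.isfinite(out.data))

    def test_drcn_loss_with_oracle_decoder_equals_ce(self, toy_batches):
        src, tgt = toy_batches
        bundle = toy_bundle("drcn").eval()

        class OracleDecoder(uda.Decoder):
            def forward(self, z):
                return Tensor(np.asarray(tgt.xt))

        bundle.method_head = OracleDecoder(md.ExtractorConfig(), 32,
                                           np.random.default_rng(0))
        loss, comps = uda.drcn_loss(bundle, src, tgt, lam=1.0)
        assert comps["adapt"] == 0.0
        assert loss.item() == comps["ce"]

    def test_mse_term_matches_brute_force(self, toy_batches):
        src, tgt = toy_batches
        bundle = toy_bundle("drcn").eval()
        loss, comps = uda.drcn_loss(bundle, src, tgt, lam=2.0)
        feats = bundle.extractor(Tensor(tgt.xt))
        recon = bundle.method_head(feats).data
        brute = float(np.sum((recon - tgt.xt) ** 2) / recon.size)
        assert comps["adapt"] == pytest.approx(brute, abs=1e-10)
        assert loss.item() == pytest.approx(comps["ce"] + 2.0 * brute, rel=1e-6)

    def test_autoencoding_smoke_reduces_mse_tenfold(self, rng):
        x = rng.standard_normal((2, 6, 64)).astype(np.float32)
        bundle = _make_bundle("drcn", md.ExtractorConfig(),
                              md.ClassifierConfig(n_classes=3), seed=1,
                              window_length=64)
        params = bundle.extractor.parameters() + bundle.method_head.parameters()
        opt = Adam(params, lr=1e-3, weight_decay=0.0)
        losses = []
        for _ in range(200):
            recon = bundle.method_head(bundle.extractor(Tensor(x)))
            loss = F.mean_squared_error(recon, x)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert losses[-1] < losses[0] / 10

    def test_missing_head_rejected(self, toy_batches):
        src, tgt = toy_batches
        with pytest.raises(ValueError, match="decoder"):
            uda.drcn_loss(toy_bundle("source_only"), src, tgt)


def test_lambda_continuity_of_all_losses(toy_batches):
    src, tgt = toy_batches
    for method, fn in (("dan", uda.dan_loss), ("dann", uda.dann_loss),
                       ("drcn", uda.drcn_loss)):
        bundle = toy_bundle(method).eval()
        at0 = fn(bundle, src, tgt, lam=0.0)[0].item()
        eps = fn(bundle, src, tgt, lam=1e-7)[0].item()
        assert eps == pytest.approx(at0, abs=1e-4)
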
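"""The three unsupervised domain-adaptation objectives.

All three combine the shared extractor/classifier with a method-specific
term weighted by the trade-off parameter lambda (default 1.0; lambda = 0
reduces every objective to source-only cross-entropy):

* divergence-minimising (DAN): multi-kernel maximum mean discrepancy between
  the source and target activations of the task-specific classifier layers
  (widths 128, 64 and n_classes);
* adversarial (DANN): a domain classifier fed through a gradient reversal
  layer, trained with binary cross-entropy on source-vs-target labels;
* reconstruction (DRCN): a transposed-convolution decoder reconstructing the
  target windows from the pooled feature, trained with mean squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat
from .models import (ClassifierConfig, ExtractorConfig, ModelBundle,
                     cross_entropy)

__all__ = [
    "SourceBatch", "TargetBatch", "DomainBatch", "KernelBank", "TradeOff",
    "mk_mmd", "gradient_reversal", "dan_loss", "dann_loss", "drcn_loss",
    "DomainClassifier", "Decoder", "build_decoder", "build_method_head",
    "median_heuristic_bandwidths",
]

#: geometric ladder around the median-heuristic base bandwidth
BANDWIDTH_LADDER = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class SourceBatch:
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self):
        if len(self.xs) == 0:
            raise ValueError("source batch must be nonempty")
        if len(self.xs) != len(self.ys):
            raise ValueError("xs and ys must align")


@dataclass(frozen=True)
class TargetBatch:
    xt: np.ndarray

    def __post_init__(self):
        if len(self.xt) == 0:
            raise ValueError("target batch must be nonempty")


@dataclass(frozen=True)
class DomainBatch:
    """Binary domain labels: source rows 0, target rows 1."""

    ds: np.ndarray
    dt: np.ndarray

    @classmethod
    def for_sizes(cls, n_source: int, n_target: int) -> "DomainBatch":
        return cls(ds=np.zeros(n_source), dt=np.ones(n_target))


@dataclass(frozen=True)
class TradeOff:
    """The lambda trade-off weight of the adaptation term."""

    lam: float = 1.0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


def median_heuristic_bandwidths(joint: np.ndarray,
                                ladder=BANDWIDTH_LADDER) -> np.ndarray:
    """Median pairwise squared distance of the joint sample times a ladder."""
    d2 = _pairwise_sq_dists_np(joint, joint)
    off_diag = d2[~np.eye(len(joint), dtype=bool)]
    base = float(np.median(off_diag)) if off_diag.size else 1.0
    if base <= 0:
        base = 1.0
    return base * np.asarray(ladder, dtype=float)


@dataclass(frozen=True)
class KernelBank:
    """Gaussian kernel family exp(-d^2 / bandwidth), equal unit weights."""

    bandwidths: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        bw = np.atleast_1d(np.asarray(self.bandwidths, dtype=float))
        if bw.size < 1 or np.any(~np.isfinite(bw)) or np.any(bw <= 0):
            raise ValueError("bandwidths must be finite positive reals")
        w = (np.ones_like(bw) if self.weights is None
             else np.asarray(self.weights, dtype=float))
        if w.shape != bw.shape:
            raise ValueError("weights must align with bandwidths")
        object.__setattr__(self, "bandwidths", bw)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_median_heuristic(cls, joint: np.ndarray,
                              ladder=BANDWIDTH_LADDER) -> "KernelBank":
        return cls(bandwidths=median_heuristic_bandwidths(joint, ladder))


def _pairwise_sq_dists_np(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = (A * A).sum(axis=1)[:, None]
    bb = (B * B).sum(axis=1)[None, :]
    return aa + bb - 2.0 * (A @ B.T)


def _joint_sq_dists(A: Tensor, B: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Distance blocks (AA, BB, AB) sliced from one joint Gram matrix.

    Computing a single Gram matrix (instead of three separate products)
    keeps the within- and cross-blocks bitwise consistent, so identical
    point sets cancel exactly; the joint diagonal is zeroed explicitly.
    """
    m = A.shape[0]
    X = concat([A, B], axis=0)
    sq = (X * X).sum(axis=1, keepdims=True)
    D = sq + sq.transpose(1, 0) - 2.0 * (X @ X.transpose(1, 0))
    D = D * (1.0 - np.eye(X.shape[0], dtype=D.data.dtype))
    return D[:m, :m], D[m:, m:], D[:m, m:]


def _ordered_sum(M: Tensor) -> Tensor:
    """Matrix sum computed as the half-sum of row and column totals.

    Equals ``M.sum()`` mathematically; the symmetric composition makes the
    result invariant to transposing ``M``, which keeps the MMD estimator
    exactly symmetric in its two arguments.
    """
    return (M.sum(axis=1).sum() + M.sum(axis=0).sum()) * 0.5


def mk_mmd(A, B, kernels: KernelBank | None = None,
           estimator: str = "unbiased") -> Tensor:
    """Multi-kernel squared maximum mean discrepancy between two batches.

    Returns a scalar tensor (differentiable when the inputs carry
    gradients): the sum over the kernel bank of the squared-MMD estimator.
    The unbiased estimator excludes the diagonal of the within-set terms
    and, when the batches have equal size, of the cross term as well;
    unequal sizes fall back to the all-pairs cross term.  Identical point
    sets give exactly zero.
    """
    A = A if isinstance(A, Tensor) else Tensor(np.asarray(A, dtype=float))
    B = B if isinstance(B, Tensor) else Tensor(np.asarray(B, dtype=float))
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("A and B must be 2-D with matching feature width")
    m, n = A.shape[0], B.shape[0]
    if estimator not in ("unbiased", "biased"):
        raise ValueError("estimator must be 'unbiased' or 'biased'")
    if estimator == "unbiased" and (m < 2 or n < 2):
        raise ValueError("the unbiased estimator needs at least 2 points per batch")
    if kernels is None:
        kernels = KernelBank.from_median_heuristic(
            np.concatenate([A.data, B.data]))

    d_aa, d_bb, d_ab = _joint_sq_dists(A, B)
    off_a = 1.0 - np.eye(m, dtype=d_aa.dtype)
    off_b = 1.0 - np.eye(n, dtype=d_bb.dtype)

    total = None
    for bw, w in zip(kernels.bandwidths, kernels.weights):
        k_aa = (d_aa * (-1.0 / bw)).exp()
        k_bb = (d_bb * (-1.0 / bw)).exp()
        k_ab = (d_ab * (-1.0 / bw)).exp()
        if estimator == "unbiased":
            term_a = _ordered_sum(k_aa * off_a) * (1.0 / (m * (m - 1)))
            term_b = _ordered_sum(k_bb * off_b) * (1.0 / (n * (n - 1)))
            if m == n:
                cross = _ordered_sum(k_ab * off_a) * (2.0 / (m * (m - 1)))
            else:
                cross = _ordered_sum(k_ab) * (2.0 / (m * n))
        else:
            term_a = _ordered_sum(k_aa) * (1.0 / (m * m))
            term_b = _ordered_sum(k_bb) * (1.0 / (n * n))
            cross = _ordered_sum(k_ab) * (2.0 / (m * n))
        part = (term_a + term_b - cross) * float(w)
        total = part if total is None else total + part
    return total


#: identity forward, gradient scaled by -beta backward
gradient_reversal = F.gradient_reversal


class DomainClassifier(nn.Module):
    """Binary domain discriminator: 128 -> 64 -> 1 logit, mirroring the
    label head's normalisation and activation."""

    def __init__(self, in_features: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        super().__init__()
        self.fc1 = nn.Linear(in_features, 64, rng)
        self.bn1 = nn.BatchNorm1d(64)
        self.act = nn.LeakyReLU(negative_slope)
        self.out = nn.Linear(64, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.act(self.bn1(self.fc1(x))))


class Decoder(nn.Module):
    """Mirror of the extractor for target reconstruction.

    A learned linear map broadcasts the pooled 128-vector back to the
    pre-pooling temporal length, then three transposed-convolution blocks
    with reversed channel widths (128, 128, 64) return to 6 channels at
    length T.
    """

    def __init__(self, extractor_config: ExtractorConfig, window_length: int,
                 rng: np.random.Generator):
        super().__init__()
        self.window_length = int(window_length)
        channels = extractor_config.channels
        kernels = extractor_config.kernel_lengths
        feat = channels[-1]
        self.expand = nn.Linear(feat, feat * self.window_length, rng)
        widths = (channels[-1],) + tuple(reversed(channels[:-1]))  # (128,128,64)
        ks = tuple(reversed(kernels))                              # (3,5,7)
        self.deconvs = []
        self.norms = []
        c_in = feat
        for c_out, k in zip(widths[1:] + (extractor_config.in_channels,), ks):
            self.deconvs.append(nn.ConvTranspose1d(c_in, c_out, k, rng))
            c_in = c_out
        self.norms = [nn.BatchNorm1d(c.weight.shape[0])
                      for c in self.deconvs[:-1]]
        self.act = nn.LeakyReLU(extractor_config.negative_slope)
        self.feat = feat

    def forward(self, z: Tensor) -> Tensor:
        if z.ndim != 2 or z.shape[1] != self.feat:
            raise ValueError(f"decoder expects (N, {self.feat}) features")
        x = self.expand(z).reshape(z.shape[0], self.feat, self.window_length)
        for deconv, norm in zip(self.deconvs[:-1], self.norms):
            x = self.act(norm(deconv(x)))
        return self.deconvs[-1](x)


def build_decoder(extractor_config: ExtractorConfig, window_length: int = 200,
                  seed: int = 0) -> Decoder:
    """Seeded construction of the reconstruction decoder."""
    return Decoder(extractor_config, window_length, np.random.default_rng(seed))


def build_method_head(method: str, extractor_config: ExtractorConfig,
                      classifier_config: ClassifierConfig, seed: int = 0,
                      window_length: int = 200) -> nn.Module | None:
    """The method-specific head: none, domain classifier, or decoder."""
    if method in ("source_only", "dan"):
        return None
    if method == "dann":
        return DomainClassifier(extractor_config.feature_dim,
                                np.random.default_rng(seed),
                                classifier_config.negative_slope)
    if method == "drcn":
        return build_decoder(extractor_config, window_length, seed)
    raise ValueError(f"unknown method {method!r}; "
                     "expected source_only, dan, dann or drcn")


def _forward_source(bundle: ModelBundle, src: SourceBatch):
    feats = bundle.extractor(Tensor(src.xs))
    logits, hidden = bundle.classifier.forward_with_hidden(feats)
    return feats, logits, hidden


def _check_shapes(src: SourceBatch, tgt: TargetBatch) -> None:
    if np.shape(src.xs)[1:] != np.shape(tgt.xt)[1:]:
        raise ValueError(f"source windows {np.shape(src.xs)[1:]} and target "
                         f"windows {np.shape(tgt.xt)[1:]} have mismatched shapes")


def dan_loss(bundle: ModelBundle, src: SourceBatch, tgt: TargetBatch,
             kernels: KernelBank | None = None, lam: float = 1.0):
    """Divergence-minimising objective: CE + lambda * sum of per-layer MK-MMD.

    The adapted layers are the classifier's task-specific states (widths
    128, 64 and n_classes); the pooled extractor feature is not adapted.
    Returns (total loss tensor, component log dict).
    """
    if bundle.method_head is not None:
        raise ValueError("the divergence method uses no method head")
    _, logits_s, hidden_s = _forward_source(bundle, src)
    ce = cross_entropy(logits_s, src.ys)
    components = {"ce": ce.item(), "adapt": 0.0}
    if lam == 0.0:
        return ce, components
    _check_shapes(src, tgt)
    feats_t = bundle.extractor(Tensor(tgt.xt))
    logits_t, hidden_t = bundle.classifier.forward_with_hidden(feats_t)
    adapt = None
    for layer_s, layer_t in zip(hidden_s + [logits_s], hidden_t + [logits_t]):
        term = mk_mmd(layer_s, layer_t, kernels=kernels)
        adapt = term if adapt is None else adapt + term
    components["adapt"] = adapt.item()
    return ce + adapt * lam, components


def dann_loss(bundle: ModelBundle, src: SourceBatch, tgt: TargetBatch,
              dom: DomainBatch | None = None, lam: float = 1.0,
              beta: float = 1.0):
    """Adversarial objective: CE + lambda * (BCE on source + BCE on target).

    The domain classifier sits behind the gradient reversal layer, so
    minimising its loss drives the extractor toward features the
    discriminator cannot separate.
    """
    if not isinstance(bundle.method_head, DomainClassifier):
        raise ValueError("the adversarial method needs a domain-classifier head")
    feats_s, logits_s, _ = _forward_source(bundle, src)
    ce = cross_entropy(logits_s, src.ys)
    components = {"ce": ce.item(), "adapt": 0.0}
    if lam == 0.0:
        return ce, components
    _check_shapes(src, tgt)
    if dom is None:
        dom = DomainBatch.for_sizes(len(src.xs), len(tgt.xt))
    feats_t = bundle.extractor(Tensor(tgt.xt))
    g = bundle.method_head
    bce_s = F.binary_cross_entropy_with_logits(
        g(gradient_reversal(feats_s, beta)), dom.ds)
    bce_t = F.binary_cross_entropy_with_logits(
        g(gradient_reversal(feats_t, beta)), dom.dt)
    adapt = bce_s + bce_t
    components["adapt"] = adapt.item()
    return ce + adapt * lam, components


def drcn_loss(bundle: ModelBundle, src: SourceBatch, tgt: TargetBatch,
              lam: float = 1.0):
    """Reconstruction objective: CE + lambda * MSE(decode(extract(xt)), xt)."""
    if not isinstance(bundle.method_head, Decoder):
        raise ValueError("the reconstruction method needs a decoder head")
    _, logits_s, _ = _forward_source(bundle, src)
    ce = cross_entropy(logits_s, src.ys)
    components = {"ce": ce.item(), "adapt": 0.0}
    if lam == 0.0:
        return ce, components
    _check_shapes(src, tgt)
    feats_t = bundle.extractor(Tensor(tgt.xt))
    recon = bundle.method_head(feats_t)
    mse = F.mean_squared_error(recon, np.asarray(tgt.xt))
    components["adapt"] = mse.item()
    return ce + mse * lam, components
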
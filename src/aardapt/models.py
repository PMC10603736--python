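"""Shared residual feature extractor and label classifier.

The extractor is a 1-D residual network for 6-channel IMU windows: three
residual blocks with temporal kernel lengths (7, 5, 3) and channel widths
(64, 128, 128), batch normalisation and leaky-ReLU activations, closed by
global average pooling over time.  Kernels slide along the time axis only;
the six sensor axes enter as input channels, so the first convolution mixes
axes.  The classifier stacks two fully connected hidden layers (128, 64)
with batch normalisation, leaky ReLU and dropout, ending in ``n_classes``
logits (softmax is applied only inside losses/metrics).

The same extractor/classifier pair, with one shared parameter set for the
source and target passes, underlies the source-only baseline and all three
domain-adaptation methods.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["ExtractorConfig", "ClassifierConfig", "ResidualBlock",
           "FeatureExtractor", "LabelClassifier", "ModelBundle",
           "build_extractor", "build_classifier", "cross_entropy",
           "save_bundle", "load_bundle"]


@dataclass(frozen=True)
class ExtractorConfig:
    in_channels: int = 6
    kernel_lengths: tuple[int, ...] = (7, 5, 3)
    channels: tuple[int, ...] = (64, 128, 128)
    negative_slope: float = 0.01

    def __post_init__(self):
        if len(self.kernel_lengths) != len(self.channels):
            raise ValueError("kernel_lengths and channels must align per block")
        if any(k % 2 == 0 or k < 1 for k in self.kernel_lengths):
            raise ValueError("kernel lengths must be odd positive integers")

    @property
    def n_blocks(self) -> int:
        return len(self.channels)

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]


@dataclass(frozen=True)
class ClassifierConfig:
    n_classes: int
    in_features: int = 128
    hidden_sizes: tuple[int, ...] = (128, 64)
    dropout_rate: float = 0.2
    negative_slope: float = 0.01

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


class ResidualBlock(nn.Module):
    """conv(k)-norm-act-conv(k)-norm plus a shortcut, then activation.

    The shortcut is the identity when channel counts match and a 1x1
    projection (convolution + normalisation) otherwise.  Same-padding keeps
    the temporal length unchanged.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, negative_slope: float = 0.01):
        super().__init__()
        self.conv1 = nn.Conv1d(in_channels, out_channels, kernel, rng)
        self.bn1 = nn.BatchNorm1d(out_channels)
        self.conv2 = nn.Conv1d(out_channels, out_channels, kernel, rng)
        self.bn2 = nn.BatchNorm1d(out_channels)
        self.act = nn.LeakyReLU(negative_slope)
        if in_channels != out_channels:
            self.proj = nn.Conv1d(in_channels, out_channels, 1, rng, bias=False)
            self.proj_bn = nn.BatchNorm1d(out_channels)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn2(self.conv2(self.act(self.bn1(self.conv1(x)))))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return self.act(h + shortcut)


class FeatureExtractor(nn.Module):
    """Residual blocks followed by global average pooling: (N,6,T) -> (N,128)."""

    def __init__(self, config: ExtractorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        blocks = []
        c_in = config.in_channels
        for k, c_out in zip(config.kernel_lengths, config.channels):
            blocks.append(ResidualBlock(c_in, c_out, k, rng,
                                        config.negative_slope))
            c_in = c_out
        self.blocks = blocks
        self.pool = nn.GlobalAvgPool1d()

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N, {self.config.in_channels}, T) input, "
                             f"got {x.shape}")
        if x.shape[2] < 1:
            raise ValueError("temporal length must be at least 1")
        for block in self.blocks:
            x = block(x)
        return self.pool(x)


class LabelClassifier(nn.Module):
    """Fully connected head 128 -> 128 -> 64 -> n_classes returning logits.

    ``forward_with_hidden`` additionally returns the post-activation hidden
    states (widths 128 and 64), the task-specific layers adapted by the
    divergence-minimising method.  Dropout follows each hidden activation
    and is active only in training mode.
    """

    def __init__(self, config: ClassifierConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        sizes = (config.in_features,) + tuple(config.hidden_sizes)
        self.linears = [nn.Linear(sizes[i], sizes[i + 1], rng)
                        for i in range(len(config.hidden_sizes))]
        self.norms = [nn.BatchNorm1d(s) for s in config.hidden_sizes]
        self.dropouts = [nn.Dropout(config.dropout_rate, rng)
                         for _ in config.hidden_sizes]
        self.act = nn.LeakyReLU(config.negative_slope)
        self.out = nn.Linear(sizes[-1], config.n_classes, rng)

    def forward_with_hidden(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        hidden = []
        for lin, norm, drop in zip(self.linears, self.norms, self.dropouts):
            x = self.act(norm(lin(x)))
            hidden.append(x)
            x = drop(x)
        return self.out(x), hidden

    def forward(self, x: Tensor) -> Tensor:
        logits, _ = self.forward_with_hidden(x)
        return logits


def build_extractor(config: ExtractorConfig | None = None, in_channels: int = 6,
                    seed: int = 0) -> FeatureExtractor:
    """Seeded construction of the residual feature extractor."""
    if config is None:
        config = ExtractorConfig(in_channels=in_channels)
    return FeatureExtractor(config, np.random.default_rng(seed))


def build_classifier(config: ClassifierConfig, seed: int = 0) -> LabelClassifier:
    """Seeded construction of the label classifier head."""
    return LabelClassifier(config, np.random.default_rng(seed))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Batch-mean cross-entropy of logits against integer labels."""
    return F.softmax_cross_entropy(logits, labels)


@dataclass
class ModelBundle:
    """Extractor + classifier (+ optional method-specific head).

    ``method_head`` is ``None`` for the source-only baseline and the
    divergence method, a domain classifier for adversarial training, or a
    decoder for reconstruction-based training.  The extractor parameters are
    a single shared set for source and target passes.
    """

    extractor: FeatureExtractor
    classifier: LabelClassifier
    method_head: nn.Module | None = None
    method: str = "source_only"
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def modules(self) -> list[nn.Module]:
        mods = [self.extractor, self.classifier]
        if self.method_head is not None:
            mods.append(self.method_head)
        return mods

    def parameters(self) -> list[Tensor]:
        return [p for m in self.modules() for p in m.parameters()]

    def train(self, mode: bool = True) -> "ModelBundle":
        for m in self.modules():
            m.train(mode)
        return self

    def eval(self) -> "ModelBundle":
        return self.train(False)

    def predict_logits(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Inference-mode logits for an array of windows (N, 6, T)."""
        self.eval()
        chunks = []
        with nn.no_grad():
            for lo in range(0, len(X), batch_size):
                feats = self.extractor(Tensor(X[lo:lo + batch_size]))
                chunks.append(self.classifier(feats).data)
        return np.concatenate(chunks) if chunks else np.empty((0, self.classifier.config.n_classes))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_logits(X).argmax(axis=1)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, module in zip(("extractor", "classifier", "head"),
                                (self.extractor, self.classifier,
                                 self.method_head)):
            if module is not None:
                state.update(module.state_dict(prefix=name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.extractor.load_state_dict(state, "extractor.")
        self.classifier.load_state_dict(state, "classifier.")
        if self.method_head is not None:
            self.method_head.load_state_dict(state, "head.")


def save_bundle(bundle: ModelBundle, path) -> None:
    """Single-file archive: parameters plus full config, method and seed."""
    config = {
        "extractor": asdict(bundle.extractor.config),
        "classifier": asdict(bundle.classifier.config),
        "method": bundle.method,
        "seed": bundle.seed,
        "meta": bundle.meta,
    }
    np.savez(path, __config__=np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8), **bundle.state_dict())


def load_bundle(path) -> ModelBundle:
    from .uda import build_method_head  # local import to avoid a cycle
    with np.load(path, allow_pickle=False) as f:
        config = json.loads(bytes(f["__config__"]).decode())
        state = {k: f[k] for k in f.files if k != "__config__"}
    ext_cfg = ExtractorConfig(**{**config["extractor"],
                                 "kernel_lengths": tuple(config["extractor"]["kernel_lengths"]),
                                 "channels": tuple(config["extractor"]["channels"])})
    clf_cfg = ClassifierConfig(**{**config["classifier"],
                                  "hidden_sizes": tuple(config["classifier"]["hidden_sizes"])})
    seed = config["seed"]
    bundle = ModelBundle(
        extractor=build_extractor(ext_cfg, seed=seed),
        classifier=build_classifier(clf_cfg, seed=seed + 1),
        method_head=build_method_head(
            config["method"], ext_cfg, clf_cfg, seed=seed + 2,
            window_length=config.get("meta", {}).get("window_length", 200)),
        method=config["method"], seed=seed, meta=config.get("meta", {}))
    bundle.load_state_dict(state)
    return bundle
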
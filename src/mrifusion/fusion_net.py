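"""Multi-sequence fusion classifier with MBConv feature extractors.

One EfficientNet-style extractor per MRI sequence (independent weights),
a late feature-fusion step (concatenate or element-wise add), and one
fully connected classification head per branch: T1, T2, and fused.
Every branch emits its own logit, so a patient missing a sequence still
receives predictions from the branches that can be computed.

The default extractor realizes the B2 stage layout: a 3×3 stem
convolution followed by seven MBConv stages (mobile inverted bottleneck
with squeeze-excitation), channels 32→16→24→48→88→120→208→352, then a
1×1 projection to the 1408-wide feature head and global average
pooling.  Compound-scaled variants B0–B4 are generated from the B0 base
by the standard width/depth rounding rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .nn import (Tensor, concat, Module, Conv2d, DepthwiseConv2d, BatchNorm2d,
                 Linear, SqueezeExcite, Sequential)

__all__ = [
    "StageSpec", "ExtractorConfig", "FeatureVector", "BranchPredictions",
    "ModelConfig", "efficientnet_stages", "b2_extractor_config",
    "reduced_extractor_config", "build_extractor", "extract_features",
    "fuse", "predict", "MultiSequenceModel", "build_model",
]

FUSED = "fused"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSpec:
    """One extractor stage: a plain convolution or a run of MBConv blocks."""
    operator: str               # "plain_conv" | "mbconv"
    kernel: int
    channels: int
    layers: int
    stride: int                 # stride of the first block in the stage
    expansion: int = 1          # MBConv expansion factor (1 or 6)
    resolution: tuple[int, int] | None = None   # input resolution, metadata

    def __post_init__(self):
        if self.operator not in ("plain_conv", "mbconv"):
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.channels <= 0:
            raise ValueError("channels must be positive")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")


@dataclass
class ExtractorConfig:
    stages: list[StageSpec]
    input_resolution: tuple[int, int] = (224, 224)
    head_width: int = 1408      # width after the post-stage 1x1 projection
    se_ratio: float = 0.25
    pretrained_init: bool = False

    def __post_init__(self):
        if self.head_width <= 0:
            raise ValueError("head_width must be positive")
        res = [s.resolution for s in self.stages if s.resolution is not None]
        for a, b in zip(res, res[1:]):
            if b[0] > a[0] or b[1] > a[1]:
                raise ValueError("stage resolutions must be non-increasing")


# Stage layout of the B0 base network; width/depth get compound-scaled.
_B0_STEM = 32
_B0_HEAD = 1280
_B0_BLOCKS = [
    # (expansion, kernel, channels, repeats, stride)
    (1, 3, 16, 1, 1),
    (6, 3, 24, 2, 2),
    (6, 5, 40, 2, 2),
    (6, 3, 80, 3, 2),
    (6, 5, 112, 3, 1),
    (6, 5, 192, 4, 2),
    (6, 3, 320, 1, 1),
]
_COEFFS = {  # width, depth multipliers
    "b0": (1.0, 1.0), "b1": (1.0, 1.1), "b2": (1.1, 1.2),
    "b3": (1.2, 1.4), "b4": (1.4, 1.8),
}


def _round_filters(filters: float, width: float, divisor: int = 8) -> int:
    filters *= width
    new = max(divisor, int(filters + divisor / 2) // divisor * divisor)
    if new < 0.9 * filters:
        new += divisor
    return int(new)


def _round_repeats(repeats: int, depth: float) -> int:
    return int(math.ceil(depth * repeats))


def efficientnet_stages(arch: str = "b2",
                        input_resolution: tuple[int, int] = (224, 224)
                        ) -> tuple[list[StageSpec], int]:
    """Stage list and head width for a compound-scaled variant b0..b4."""
    if arch not in _COEFFS:
        raise ValueError(f"unknown architecture {arch!r}; choose from {sorted(_COEFFS)}")
    width, depth = _COEFFS[arch]
    h, w = input_resolution
    stages = [StageSpec("plain_conv", 3, _round_filters(_B0_STEM, width), 1,
                        stride=2, resolution=(h, w))]
    h, w = h // 2, w // 2
    for exp, k, c, r, s in _B0_BLOCKS:
        stages.append(StageSpec("mbconv", k, _round_filters(c, width),
                                _round_repeats(r, depth), stride=s,
                                expansion=exp, resolution=(h, w)))
        if s == 2:
            h, w = h // 2, w // 2
    return stages, _round_filters(_B0_HEAD, width)


def b2_extractor_config(input_resolution: tuple[int, int] = (224, 224),
                        strict_table: bool = False) -> ExtractorConfig:
    """The default B2 extractor.

    With ``strict_table=True`` the post-stage 1×1 projection is dropped
    and global pooling acts directly on the 352-channel stage-8 output.
    """
    stages, head = efficientnet_stages("b2", input_resolution)
    if strict_table:
        head = stages[-1].channels
    return ExtractorConfig(stages=stages, input_resolution=input_resolution,
                           head_width=head)


def reduced_extractor_config(input_resolution: tuple[int, int] = (96, 96),
                             head_width: int = 64) -> ExtractorConfig:
    """Small extractor for desk-scale CPU experiments on 96×96 slices.

    Same block grammar as the full network (stem + MBConv1/MBConv6 with
    squeeze-excitation), four stages deep, 64-wide feature head.
    """
    h, w = input_resolution
    stages = [
        StageSpec("plain_conv", 3, 8, 1, stride=2, resolution=(h, w)),
        StageSpec("mbconv", 3, 8, 1, stride=1, expansion=1, resolution=(h // 2, w // 2)),
        StageSpec("mbconv", 3, 16, 1, stride=2, expansion=6, resolution=(h // 2, w // 2)),
        StageSpec("mbconv", 5, 24, 1, stride=2, expansion=6, resolution=(h // 4, w // 4)),
        StageSpec("mbconv", 3, 32, 1, stride=2, expansion=6, resolution=(h // 8, w // 8)),
    ]
    return ExtractorConfig(stages=stages, input_resolution=input_resolution,
                           head_width=head_width)


# ---------------------------------------------------------------------------
# features and predictions
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    values: np.ndarray
    source: str                 # "T1" | "T2" | "fused"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    @property
    def dim(self) -> int:
        return int(self.values.size)


@dataclass
class BranchPredictions:
    """Per-branch logits and sigmoid probabilities."""
    logits: dict[str, float]
    probabilities: dict[str, float]

    def __post_init__(self):
        for k, s in self.logits.items():
            p = self.probabilities[k]
            if abs(p - 1.0 / (1.0 + math.exp(-s))) > 1e-9:
                raise ValueError(f"probability of branch {k} is not sigmoid(logit)")

    @property
    def branches(self) -> list[str]:
        return list(self.logits)


@dataclass
class ModelConfig:
    sequence_names: tuple[str, ...] = ("T1", "T2")
    fusion_method: str = "concatenate"      # "concatenate" | "add"
    extractor: ExtractorConfig = field(default_factory=b2_extractor_config)
    seed: int = 0

    def __post_init__(self):
        if self.fusion_method not in ("concatenate", "add"):
            raise ValueError(f"unknown fusion method {self.fusion_method!r}")
        if len(self.sequence_names) < 1:
            raise ValueError("at least one sequence required")


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class MBConvBlock(Module):
    """Mobile inverted bottleneck: expand → depthwise → SE → project.

    Residual connection when stride is 1 and channels are preserved.
    """

    def __init__(self, c_in: int, c_out: int, expansion: int, kernel: int,
                 stride: int, se_ratio: float, rng: np.random.Generator):
        super().__init__()
        c_mid = c_in * expansion
        self.expand = None
        if expansion != 1:
            self.expand = Conv2d(c_in, c_mid, 1, rng=rng)
            self.bn0 = BatchNorm2d(c_mid)
        self.dw = DepthwiseConv2d(c_mid, kernel, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(c_mid)
        self.se = SqueezeExcite(c_mid, max(1, int(c_in * se_ratio)), rng=rng)
        self.project = Conv2d(c_mid, c_out, 1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.residual = stride == 1 and c_in == c_out

    def forward(self, x: Tensor) -> Tensor:
        h = x
        if self.expand is not None:
            h = self.bn0(self.expand(h)).silu()
        h = self.bn1(self.dw(h)).silu()
        h = self.se(h)
        h = self.bn2(self.project(h))
        if self.residual:
            h = h + x
        return h


class FeatureExtractor(Module):
    """Stage stack + optional 1×1 head projection + global average pool."""

    def __init__(self, config: ExtractorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        blocks: list[Module] = []
        self.stage_slices: list[tuple[int, int]] = []
        c_prev = 3
        for spec in config.stages:
            start = len(blocks)
            if spec.operator == "plain_conv":
                for _ in range(spec.layers):
                    blocks.append(Sequential(
                        Conv2d(c_prev, spec.channels, spec.kernel,
                               stride=spec.stride, rng=rng),
                        BatchNorm2d(spec.channels)))
                    c_prev = spec.channels
            else:
                for i in range(spec.layers):
                    stride = spec.stride if i == 0 else 1
                    blocks.append(MBConvBlock(c_prev, spec.channels,
                                              spec.expansion, spec.kernel,
                                              stride, config.se_ratio, rng))
                    c_prev = spec.channels
            self.stage_slices.append((start, len(blocks)))
        self.blocks = blocks
        self.head = None
        if config.head_width != c_prev:
            self.head = Conv2d(c_prev, config.head_width, 1, rng=rng)
            self.head_bn = BatchNorm2d(config.head_width)
        self.out_dim = config.head_width

    @property
    def stage_channels(self) -> list[int]:
        return [s.channels for s in self.config.stages]

    def forward(self, x: Tensor) -> Tensor:
        """(N, 3, H, W) -> (N, head_width) pooled features."""
        h = x
        for i, b in enumerate(self.blocks):
            h = b(h)
            if isinstance(b, Sequential):     # stem conv: BN then activation
                h = h.silu()
        if self.head is not None:
            h = self.head_bn(self.head(h)).silu()
        return h.global_avg_pool()

    def stage_outputs(self, x: Tensor) -> list[Tensor]:
        """Per-stage activations, for architecture conformance checks."""
        outs = []
        h = x
        for start, end in self.stage_slices:
            for b in self.blocks[start:end]:
                h = b(h)
                if isinstance(b, Sequential):
                    h = h.silu()
            outs.append(h)
        return outs


def build_extractor(config: ExtractorConfig,
                    rng: np.random.Generator | None = None) -> FeatureExtractor:
    """Construct a feature extractor from its stage configuration."""
    if config.pretrained_init:
        raise ValueError("no pretrained weight source is configured; "
                         "use random initialization or load a checkpoint")
    return FeatureExtractor(config, rng or np.random.default_rng())


def extract_features(extractor: FeatureExtractor, image: np.ndarray,
                     source: str = "T1") -> FeatureVector:
    """Pooled feature vector for one (3, H, W) image, in eval mode."""
    x = _check_image(image, extractor.config.input_resolution)
    extractor.eval()
    out = extractor(Tensor(x[None]))
    return FeatureVector(out.data[0], source=source)


def _check_image(image: np.ndarray, resolution: tuple[int, int]) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = np.repeat(image[None], 3, axis=0)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError(f"expected (3, H, W) image, got shape {image.shape}")
    if tuple(image.shape[1:]) != tuple(resolution):
        raise ValueError(f"image resolution {image.shape[1:]} does not match "
                         f"configured {tuple(resolution)}")
    return image


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def fuse(features: list[FeatureVector], method: str = "concatenate") -> FeatureVector:
    """Late fusion of per-sequence feature vectors.

    ``concatenate`` joins the vectors end-to-end in input order;
    ``add`` sums them element-wise (equal dims required).
    """
    if len(features) < 2:
        raise ValueError("fusion requires at least two feature vectors")
    if method == "concatenate":
        vals = np.concatenate([f.values for f in features])
    elif method == "add":
        dims = {f.dim for f in features}
        if len(dims) != 1:
            raise ValueError(f"add fusion requires equal dims, got "
                             f"{[f.dim for f in features]}")
        vals = np.sum([f.values for f in features], axis=0)
    else:
        raise ValueError(f"unknown fusion method {method!r}")
    return FeatureVector(vals, source=FUSED)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class MultiSequenceModel(Module):
    """Independent extractor per sequence + one FC classifier per branch."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.extractors: dict[str, FeatureExtractor] = {}
        self.classifiers: dict[str, Linear] = {}
        d = config.extractor.head_width
        for name in config.sequence_names:
            self.extractors[name] = build_extractor(config.extractor, rng)
            self.classifiers[name] = Linear(d, 1, rng=rng, name=f"cls_{name}")
        fused_dim = (d * len(config.sequence_names)
                     if config.fusion_method == "concatenate" else d)
        self.fused_classifier = Linear(fused_dim, 1, rng=rng, name="cls_fused")
        # register dict members for Module traversal
        self._children = list(self.extractors.values()) + list(self.classifiers.values())

    def forward_branches(self, images: dict[str, Tensor]) -> dict[str, Tensor]:
        """Batch logits per branch; fused branch iff all sequences supplied.

        images: map sequence name -> (N, 3, H, W) Tensor.  All supplied
        batches must have equal N for the fused branch to be built.
        """
        names = [n for n in self.config.sequence_names if n in images]
        if not names:
            raise ValueError(f"no recognized sequence among {list(images)}; "
                             f"configured: {list(self.config.sequence_names)}")
        feats = {n: self.extractors[n](images[n]) for n in names}
        logits = {n: self.classifiers[n](feats[n]).reshape(-1) for n in names}
        if len(names) == len(self.config.sequence_names):
            sizes = {feats[n].shape[0] for n in names}
            if len(sizes) == 1:
                if self.config.fusion_method == "concatenate":
                    f = concat([feats[n] for n in names], axis=1)
                else:
                    f = feats[names[0]]
                    for n in names[1:]:
                        f = f + feats[n]
                logits[FUSED] = self.fused_classifier(f).reshape(-1)
        return logits


def build_model(config: ModelConfig) -> MultiSequenceModel:
    return MultiSequenceModel(config)


def predict(model: MultiSequenceModel, sequences: dict[str, np.ndarray]
            ) -> BranchPredictions:
    """Single-patient inference: one logit per supplied sequence branch.

    The fused branch is present only when every configured sequence is
    supplied.  Inference is pure — no parameters change.
    """
    res = model.config.extractor.input_resolution
    images = {name: Tensor(_check_image(img, res)[None])
              for name, img in sequences.items()
              if name in model.config.sequence_names}
    if not images:
        raise ValueError(f"no recognized sequence among {list(sequences)}")
    model.eval()
    logits = model.forward_branches(images)
    out_logits = {k: float(v.data[0]) for k, v in logits.items()}
    probs = {k: 1.0 / (1.0 + math.exp(-s)) for k, s in out_logits.items()}
    return BranchPredictions(logits=out_logits, probabilities=probs)
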
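"""DeepLabv3+ with optional CBAM and ECA attention.

Encoder-decoder semantic segmentation: a small residual backbone with total
output stride 16, an Atrous Spatial Pyramid Pooling (ASPP) head, and a
decoder that fuses upsampled ASPP context with stride-4 low-level features.
The two attention blocks sit at the positions the architecture prescribes:
CBAM transforms the backbone's final feature map (by default before ASPP),
and ECA transforms the low-level feature path immediately before the
decoder's concatenation.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.layers import BatchNorm2d, Conv2d, Module
from .attention import CBAM, ECA

__all__ = ["ModelConfig", "DeepLabV3Plus", "build_model", "predict_mask",
           "save_checkpoint", "load_checkpoint", "ConfigError"]

TOTAL_STRIDE = 16
_BACKBONE_WIDTHS = {"tiny8": 8, "tiny16": 16, "tiny24": 24, "tiny32": 32}


class ConfigError(ValueError):
    """Invalid model configuration."""


@dataclass
class ModelConfig:
    n_classes: int = 5
    backbone: str = "tiny16"
    aspp_rates: tuple = (6, 12, 18)
    use_cbam: bool = True
    use_eca: bool = True
    cbam_reduction: int = 16
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    input_size: int = 128
    cbam_position: str = "before_aspp"   # or "after_aspp"

    def validate(self):
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if not self.aspp_rates:
            raise ConfigError("aspp_rates must be nonempty")
        if self.cbam_reduction < 1:
            raise ConfigError("cbam_reduction must be >= 1")
        if self.backbone not in _BACKBONE_WIDTHS:
            raise ConfigError(f"unknown backbone {self.backbone!r}; "
                              f"choose from {sorted(_BACKBONE_WIDTHS)}")
        if self.input_size % TOTAL_STRIDE:
            raise ConfigError(
                f"input_size {self.input_size} not divisible by encoder stride {TOTAL_STRIDE}")
        if self.cbam_position not in ("before_aspp", "after_aspp"):
            raise ConfigError("cbam_position must be 'before_aspp' or 'after_aspp'")
        return self

    def to_json(self) -> str:
        d = asdict(self)
        d["aspp_rates"] = list(self.aspp_rates)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["aspp_rates"] = tuple(d.get("aspp_rates", (6, 12, 18)))
        return cls(**d)


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, k=3, stride=1, dilation=1, rng=None):
        super().__init__()
        pad = dilation * (k // 2)
        self.conv = Conv2d(in_ch, out_ch, k, stride=stride, padding=pad,
                           dilation=dilation, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class ResidualBlock(Module):
    """Two 3x3 conv-BN units with an identity or projected skip."""

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x):
        out = ag.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        skip = x if self.proj is None else self.proj_bn(self.proj(x))
        return ag.relu(ag.add(out, skip))


class Backbone(Module):
    """Residual encoder, output stride 16; exposes stride-4 low-level features."""

    def __init__(self, width, rng=None):
        super().__init__()
        w = width
        self.stem = ConvBNReLU(3, w, stride=2, rng=rng)          # /2
        self.layer1 = ResidualBlock(w, 2 * w, stride=2, rng=rng)  # /4  -> low level
        self.layer2 = ResidualBlock(2 * w, 4 * w, stride=2, rng=rng)  # /8
        self.layer3 = ResidualBlock(4 * w, 4 * w, stride=2, rng=rng)  # /16
        self.low_channels = 2 * w
        self.out_channels = 4 * w

    def forward(self, x):
        x = self.stem(x)
        low = self.layer1(x)
        x = self.layer2(low)
        x = self.layer3(x)
        return low, x


class ASPP(Module):
    """Atrous Spatial Pyramid Pooling: 1x1 + dilated 3x3 branches + image pooling."""

    def __init__(self, in_ch, out_ch, rates, rng=None):
        super().__init__()
        self.branch1 = ConvBNReLU(in_ch, out_ch, k=1, rng=rng)
        self.atrous = [ConvBNReLU(in_ch, out_ch, k=3, dilation=r, rng=rng) for r in rates]
        self.image_pool_conv = ConvBNReLU(in_ch, out_ch, k=1, rng=rng)
        n_branches = 2 + len(self.atrous)
        self.project = ConvBNReLU(n_branches * out_ch, out_ch, k=1, rng=rng)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        feats = [self.branch1(x)] + [b(x) for b in self.atrous]
        pooled = ag.mean(x, axis=(2, 3), keepdims=True)
        pooled = self.image_pool_conv(pooled)
        feats.append(ag.upsample_bilinear(pooled, (h, w)))
        return self.project(ag.concat(feats, axis=1))


class DeepLabV3Plus(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        width = _BACKBONE_WIDTHS[config.backbone]
        self.backbone = Backbone(width, rng=rng)
        c_high = self.backbone.out_channels
        aspp_out = c_high
        self.cbam = CBAM(c_high if config.cbam_position == "before_aspp" else aspp_out,
                         reduction=min(config.cbam_reduction, c_high),
                         rng=rng) if config.use_cbam else None
        self.aspp = ASPP(c_high, aspp_out, config.aspp_rates, rng=rng)
        self.eca = ECA(self.backbone.low_channels, gamma=config.eca_gamma,
                       b=config.eca_b, rng=rng) if config.use_eca else None
        dec_low = max(8, width)
        self.low_project = ConvBNReLU(self.backbone.low_channels, dec_low, k=1, rng=rng)
        self.refine1 = ConvBNReLU(aspp_out + dec_low, 2 * width, k=3, rng=rng)
        self.refine2 = ConvBNReLU(2 * width, 2 * width, k=3, rng=rng)
        self.classifier = Conv2d(2 * width, config.n_classes, 1, rng=rng)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[2] % TOTAL_STRIDE or x.shape[3] % TOTAL_STRIDE:
            raise ConfigError(
                f"input spatial size {x.shape[2:]} not divisible by stride {TOTAL_STRIDE}")
        h, w = x.shape[2], x.shape[3]
        low, high = self.backbone(x)
        if self.cbam is not None and self.config.cbam_position == "before_aspp":
            high = self.cbam(high)
        high = self.aspp(high)
        if self.cbam is not None and self.config.cbam_position == "after_aspp":
            high = self.cbam(high)
        if self.eca is not None:
            low = self.eca(low)
        low = self.low_project(low)
        high = ag.upsample_bilinear(high, (low.shape[2], low.shape[3]))
        fused = self.refine2(self.refine1(ag.concat([high, low], axis=1)))
        logits = self.classifier(fused)
        return ag.upsample_bilinear(logits, (h, w))

    def attention_blocks(self):
        """Enumerate inserted attention blocks and their architectural positions."""
        blocks = []
        if self.cbam is not None:
            pos = ("backbone_output->CBAM->ASPP"
                   if self.config.cbam_position == "before_aspp"
                   else "ASPP->CBAM->decoder")
            blocks.append(("CBAM", pos))
        if self.eca is not None:
            blocks.append(("ECA", "low_level->ECA->decoder_concat"))
        return blocks


def build_model(config: ModelConfig, seed: int = 0) -> DeepLabV3Plus:
    return DeepLabV3Plus(config, seed=seed)


def predict_mask(model: DeepLabV3Plus, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax label mask for one H x W x 3 image in [0,1] or uint8.

    Ties in the logits break toward the lowest label id.
    """
    from .train import prepare_image
    x = prepare_image(image)
    model.eval()
    logits = model(Tensor(x[None]))
    return np.argmax(logits.data[0], axis=0).astype(np.uint8)


def save_checkpoint(model: DeepLabV3Plus, path):
    path = Path(path)
    state = {k: np.ascontiguousarray(v) for k, v in model.state_arrays().items()}
    with open(path, "wb") as fh:
        pickle.dump({"state": state}, fh)
    path.with_suffix(path.suffix + ".json").write_text(model.config.to_json())


def load_checkpoint(path, seed: int = 0) -> DeepLabV3Plus:
    path = Path(path)
    config = ModelConfig.from_json(path.with_suffix(path.suffix + ".json").read_text())
    model = build_model(config, seed=seed)
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    model.load_state_arrays(payload["state"])
    return model
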
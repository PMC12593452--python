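"""3D encoder-decoder segmentation backbone.

Four encoder levels of residual double-conv blocks (Conv3x3x3 → GroupNorm →
PReLU, twice, with an additive identity / 1x1x1-projected skip), stride-2
strided-conv downsampling between levels, a bottleneck double-conv whose
output is the latent grid Z handed to the causal layer, and a mirrored
decoder (transposed-conv upsampling, skip concatenation, double conv)
ending in a 1x1x1 softmax head.

The channel plan at ``width_scale=1`` is 32/64/128/256 with a 320-channel
bottleneck; the latent grid sits at 1/8 of the input resolution, so input
spatial dims must be divisible by 8. ``width_scale`` shrinks every width
proportionally for desk-scale models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = ["BackboneConfig", "Backbone", "build"]


@dataclass
class BackboneConfig:
    in_channels: int = 4
    n_classes: int = 4
    level_channels: tuple[int, ...] = (32, 64, 128, 256)
    bottleneck_channels: int = 320
    norm_groups: int = 8
    width_scale: float = 1.0

    def __post_init__(self):
        if len(self.level_channels) != 4:
            raise ValueError("exactly four encoder levels are required")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        for c in self.scaled_channels + (self.scaled_bottleneck,):
            if c % self.norm_groups:
                raise ValueError(
                    f"channel count {c} not divisible by norm_groups="
                    f"{self.norm_groups} (at width_scale={self.width_scale})")

    @property
    def scaled_channels(self) -> tuple[int, ...]:
        return tuple(max(self.norm_groups,
                         int(round(c * self.width_scale)))
                     for c in self.level_channels)

    @property
    def scaled_bottleneck(self) -> int:
        return max(self.norm_groups,
                   int(round(self.bottleneck_channels * self.width_scale)))


class _ResidualDoubleConv(nn.Module):
    """Conv-GN-PReLU ×2 with an additive skip around the pair."""

    def __init__(self, cin: int, cout: int, groups: int,
                 rng: np.random.Generator):
        self.conv1 = nn.Conv3d(cin, cout, k=3, rng=rng)
        self.gn1 = nn.GroupNorm(cout, groups)
        self.act1 = nn.PReLU(cout)
        self.conv2 = nn.Conv3d(cout, cout, k=3, rng=rng)
        self.gn2 = nn.GroupNorm(cout, groups)
        self.act2 = nn.PReLU(cout)
        self.proj = (nn.Conv3d(cin, cout, k=1, rng=rng)
                     if cin != cout else None)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        skip = self.proj(x) if self.proj is not None else x
        h = self.act1(self.gn1(self.conv1(x)))
        h = self.gn2(self.conv2(h))
        return self.act2(h + skip)


class Backbone(nn.Module):
    """Encoder-decoder with a latent interface at 1/8 resolution."""

    DOWNSAMPLE_FACTOR = 8

    def __init__(self, config: BackboneConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        ch = config.scaled_channels
        kb = config.scaled_bottleneck
        g = config.norm_groups
        self.config = config

        self.enc = [
            _ResidualDoubleConv(config.in_channels, ch[0], g, rng),
            _ResidualDoubleConv(ch[1], ch[1], g, rng),
            _ResidualDoubleConv(ch[2], ch[2], g, rng),
            _ResidualDoubleConv(ch[3], ch[3], g, rng),
        ]
        self.down = [
            nn.Conv3d(ch[0], ch[1], k=3, stride=2, rng=rng),
            nn.Conv3d(ch[1], ch[2], k=3, stride=2, rng=rng),
            nn.Conv3d(ch[2], ch[3], k=3, stride=2, rng=rng),
        ]
        self.bottleneck = _ResidualDoubleConv(ch[3], kb, g, rng)
        # decoder level 4 sits at bottleneck resolution: 1x1x1 projection
        # then concat with the encoder-4 skip
        self.dec4_proj = nn.Conv3d(kb, ch[3], k=1, rng=rng)
        self.dec4 = _ResidualDoubleConv(2 * ch[3], ch[3], g, rng)
        self.up3 = nn.ConvTranspose3d2x(ch[3], ch[2], rng=rng)
        self.dec3 = _ResidualDoubleConv(2 * ch[2], ch[2], g, rng)
        self.up2 = nn.ConvTranspose3d2x(ch[2], ch[1], rng=rng)
        self.dec2 = _ResidualDoubleConv(2 * ch[1], ch[1], g, rng)
        self.up1 = nn.ConvTranspose3d2x(ch[1], ch[0], rng=rng)
        self.dec1 = _ResidualDoubleConv(2 * ch[0], ch[0], g, rng)
        self.head = nn.Conv3d(ch[0], config.n_classes, k=1, rng=rng)

    # -- interface ----------------------------------------------------------
    @property
    def latent_channels(self) -> int:
        return self.config.scaled_bottleneck

    def _check_input(self, x):
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, X, Y, Z) input, "
                f"got {tuple(x.shape)}")
        for s in x.shape[2:]:
            if s % self.DOWNSAMPLE_FACTOR:
                raise ValueError(
                    f"spatial dims must be divisible by "
                    f"{self.DOWNSAMPLE_FACTOR}; pad the input (got "
                    f"{tuple(x.shape[2:])})")

    def encode(self, x: nn.Tensor) -> tuple[nn.Tensor, list[nn.Tensor]]:
        """Return the latent grid Z (N, K, X/8, Y/8, Z/8) and skip features."""
        x = nn.astensor(x)
        self._check_input(x)
        s1 = self.enc[0](x)
        s2 = self.enc[1](self.down[0](s1))
        s3 = self.enc[2](self.down[1](s2))
        s4 = self.enc[3](self.down[2](s3))
        z = self.bottleneck(s4)
        return z, [s1, s2, s3, s4]

    def decode(self, z: nn.Tensor, skips: list[nn.Tensor]) -> nn.Tensor:
        """Latent + skips -> class logits at input resolution."""
        s1, s2, s3, s4 = skips
        h = self.dec4(nn.concat([self.dec4_proj(z), s4], axis=1))
        h = self.dec3(nn.concat([self.up3(h), s3], axis=1))
        h = self.dec2(nn.concat([self.up2(h), s2], axis=1))
        h = self.dec1(nn.concat([self.up1(h), s1], axis=1))
        return self.head(h)

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor, list]:
        """Full pass: (logits, latent, skips)."""
        z, skips = self.encode(x)
        return self.decode(z, skips), z, skips

    def predict(self, x) -> np.ndarray:
        """Softmax class probabilities (N, C, X, Y, Z) as numpy."""
        logits, _, _ = self.forward(nn.Tensor(np.asarray(x, np.float32)))
        return nn.softmax(logits, axis=1).data


def build(config: BackboneConfig, seed: int = 0) -> Backbone:
    """Construct a backbone with seeded deterministic initialisation."""
    return Backbone(config, seed=seed)
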
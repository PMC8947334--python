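"""Dual-modality 3-D U-Net variants for thrombus segmentation.

Five variants share one fully convolutional encoder-decoder skeleton
(3x3x3 convolutions with padding 1, 2x max pooling, 2x trilinear
up-sampling with aligned corners, channel widths doubling per level):

* ``unet2ch`` -- a single encoder fed NCCT and CTA as two input channels,
  so the modalities mix in the first convolution;
* ``concat`` / ``add`` / ``weighted_sum`` -- one encoder per modality;
  the encoders' features are fused at the bottleneck and at every skip
  level with the named operator, then decoded jointly.  Weighted-sum
  fusion learns one scalar pair (k1, k2) per channel per fusion site,
  F_i = k1 A_i + k2 B_i, i.e. a 1x1x1 convolution across the pair -- the
  inductive bias of an explicit per-modality weight at negligible
  parameter cost over plain addition;
* ``unet_ncct_only`` -- the single-modality baseline (NCCT channel only).

Channel widths start from a configurable base (absolute parameter counts
scale with it; the ordering ncct-only < 2-channel < add ~ weighted-sum <
concatenate is width-independent).  Because skip connections constrain
acceptable input sizes, crops are zero-padded to multiples of 2**depth
before the forward pass and predictions un-padded afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Tuple

import numpy as np

from . import nn
from .boxes import CropRecord, pad_to_acceptable, unpad

VARIANTS = ("unet2ch", "concat", "add", "weighted_sum", "unet_ncct_only")


class NetError(ValueError):
    """Raised for invalid network configuration or input."""


@dataclass(frozen=True)
class NetConfig:
    variant: str = "weighted_sum"
    depth: int = 4
    base_width: int = 8

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise NetError(f"unknown variant {self.variant!r}")
        if self.depth < 1 or self.base_width < 1:
            raise NetError("depth and base width must be >= 1")


def weighted_sum_fuse(a: np.ndarray, b: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Fuse two (C, D, H, W) feature grids channel-wise: F_i = k1 A_i + k2 B_i.

    ``kernels`` has shape (C, 2), one (k1, k2) pair per channel.  With all
    pairs (1, 0) the result is A; with (1, 1) it is the add-fusion A + B.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if a.shape != b.shape:
        raise NetError(f"fusion shape mismatch {a.shape} vs {b.shape}")
    if kernels.shape != (a.shape[0], 2):
        raise NetError(f"need one (k1, k2) pair per channel, got {kernels.shape}")
    k1 = kernels[:, 0, None, None, None]
    k2 = kernels[:, 1, None, None, None]
    return k1 * a + k2 * b


class _Decoder:
    """Shared decoder: upsample, concatenate the skip, convolve."""

    def __init__(self, skip_widths: List[int], bottleneck_width: int,
                 base: int, rng: np.random.Generator):
        self.blocks = []
        up_width = bottleneck_width
        for level in reversed(range(len(skip_widths))):
            out_width = base * 2**level
            self.blocks.append(
                nn.ConvBlock(up_width + skip_widths[level], out_width, rng=rng)
            )
            up_width = out_width
        self.head = nn.Conv3d(up_width, 1, kernel=1, padding=0, rng=rng)

    def __call__(self, bottleneck: nn.Tensor, skips: List[nn.Tensor]) -> nn.Tensor:
        x = bottleneck
        for block, skip in zip(self.blocks, reversed(skips)):
            x = nn.upsample_trilinear2(x)
            x = block(nn.concat(x, skip))
        return self.head(x)

    def parameters(self) -> List[nn.Tensor]:
        params: List[nn.Tensor] = []
        for b in self.blocks:
            params += b.parameters()
        return params + self.head.parameters()


class _Encoder:
    def __init__(self, in_channels: int, base: int, depth: int,
                 rng: np.random.Generator):
        self.blocks = []
        width = in_channels
        for level in range(depth):
            self.blocks.append(nn.ConvBlock(width, base * 2**level, rng=rng))
            width = base * 2**level
        self.bottleneck = nn.ConvBlock(width, base * 2**depth, rng=rng)

    def __call__(self, x: nn.Tensor) -> Tuple[List[nn.Tensor], nn.Tensor]:
        skips = []
        for block in self.blocks:
            x = block(x)
            skips.append(x)
            x = nn.maxpool2(x)
        return skips, self.bottleneck(x)

    def parameters(self) -> List[nn.Tensor]:
        params: List[nn.Tensor] = []
        for b in self.blocks:
            params += b.parameters()
        return params + self.bottleneck.parameters()


class SegNet:
    """One of the five U-Net variants; built by :func:`build_network`."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        base, depth = cfg.base_width, cfg.depth
        self.fusion_weights: List[Tuple[nn.Tensor, nn.Tensor]] = []
        skip_widths = [base * 2**level for level in range(depth)]
        bott = base * 2**depth

        if cfg.variant in ("unet2ch", "unet_ncct_only"):
            in_ch = 2 if cfg.variant == "unet2ch" else 1
            self.encoder = _Encoder(in_ch, base, depth, rng)
            self.encoder_b = None
            self.decoder = _Decoder(skip_widths, bott, base, rng)
        else:
            self.encoder = _Encoder(1, base, depth, rng)
            self.encoder_b = _Encoder(1, base, depth, rng)
            if cfg.variant == "concat":
                skip_widths = [2 * w for w in skip_widths]
                bott *= 2
            elif cfg.variant == "weighted_sum":
                for width in [base * 2**level for level in range(depth)] + [base * 2**depth]:
                    k1 = nn.parameter(np.ones(width, dtype=np.float32))
                    k2 = nn.parameter(np.ones(width, dtype=np.float32))
                    self.fusion_weights.append((k1, k2))
            self.decoder = _Decoder(skip_widths, bott, base, rng)

    def _fuse(self, a: nn.Tensor, b: nn.Tensor, site: int) -> nn.Tensor:
        if self.cfg.variant == "concat":
            return nn.concat(a, b)
        if self.cfg.variant == "add":
            return nn.add(a, b)
        k1, k2 = self.fusion_weights[site]
        return nn.channel_weighted_sum(a, b, k1, k2)

    def forward(self, ncct: np.ndarray, cta: np.ndarray | None = None) -> nn.Tensor:
        """Logits (1, D, H, W) for box-local crops of acceptable size."""
        if any(s % 2**self.cfg.depth for s in ncct.shape):
            raise NetError(
                f"input extents {ncct.shape} must be multiples of {2**self.cfg.depth}"
            )
        ncct = np.asarray(ncct, dtype=np.float32)
        if cta is not None:
            cta = np.asarray(cta, dtype=np.float32)
        if self.cfg.variant == "unet_ncct_only":
            skips, bottleneck = self.encoder(nn.Tensor(ncct[None]))
            return self.decoder(bottleneck, skips)
        if cta is None:
            raise NetError(f"variant {self.cfg.variant} requires a CTA channel")
        if self.cfg.variant == "unet2ch":
            x = nn.Tensor(np.stack([ncct, cta]))
            skips, bottleneck = self.encoder(x)
            return self.decoder(bottleneck, skips)
        skips_a, bott_a = self.encoder(nn.Tensor(ncct[None]))
        skips_b, bott_b = self.encoder_b(nn.Tensor(cta[None]))
        skips = [self._fuse(a, b, i) for i, (a, b) in enumerate(zip(skips_a, skips_b))]
        bottleneck = self._fuse(bott_a, bott_b, len(skips))
        return self.decoder(bottleneck, skips)

    def parameters(self) -> List[nn.Tensor]:
        params = self.encoder.parameters()
        if self.encoder_b is not None:
            params += self.encoder_b.parameters()
        for k1, k2 in self.fusion_weights:
            params += [k1, k2]
        return params + self.decoder.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: List[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise NetError("state does not match the architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise NetError("state does not match the architecture")
            p.data = np.asarray(a, dtype=p.data.dtype).copy()


def build_network(cfg: NetConfig, seed: int = 0) -> SegNet:
    """Instantiate a variant with seeded He-normal initialisation."""
    return SegNet(cfg, np.random.default_rng(seed))


def predict_mask(
    model: SegNet,
    ncct_crop: np.ndarray,
    cta_crop: np.ndarray | None = None,
    threshold: float = 0.5,
) -> np.ndarray:
    """Binarized prediction for a box-local crop of any size.

    The crop is zero-padded to the nearest acceptable size, passed through
    the network, binarized as sigmoid(logit) > threshold (strict, so a zero
    logit is background), and un-padded back to the crop shape.
    """
    padded, record = pad_to_acceptable(np.asarray(ncct_crop, dtype=float), model.cfg.depth)
    cta_padded = None
    if cta_crop is not None:
        cta_padded, _ = pad_to_acceptable(np.asarray(cta_crop, dtype=float), model.cfg.depth)
    logits = model.forward(padded, cta_padded)
    prob = nn.sigmoid(logits.data[0])
    return unpad(prob > threshold, record)


def save_checkpoint(model: SegNet, path: str | Path) -> Path:
    """Persist config + weights (npz with an embedded JSON config)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(asdict(model.cfg)), **arrays)
    return path


def load_checkpoint(path: str | Path) -> SegNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = NetConfig(**json.loads(str(data["config"])))
        model = build_network(cfg)
        n = len(model.parameters())
        model.load_state_arrays([data[f"p{i}"] for i in range(n)])
    return model
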
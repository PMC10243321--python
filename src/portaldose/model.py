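"""The portal-image-to-dose model: U-net plus True Dose Modulation layer.

The U-net is an encoder/decoder with skip connections: four 2x2 max-pooling
levels, two 3x3 conv+ReLU layers per block, kernel counts 8-16-32-64 along
the encoder and 128 in the bottleneck, mirrored in the decoder, and a final
block of three convolutions ending in a linear 1x1 single-kernel layer that
collapses the channels to one dose plane.  No dropout, batch normalization
or loss regularization are used.

The flood-field correction erases the beam's off-axis modulation from the
input image, so the dose "horn" is positional information the network cannot
observe.  The True Dose Modulation (TDM) layer restores it: a non-trainable
positive map, computed as the ratio of the reference dose of a large open
square beam to the stage-1 network's inference of it, multiplied onto the
network output pixel by pixel (Hadamard product).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .core import DoseDistribution, GridSpec, PortalImage
from .nn import DTYPE, Adam, Conv2D, MaxPool2, Param, ReLU, Upsample2
from .preprocessing import NormalizationFactors, calibrate, default_crop_px, edge_correct, normalize

__all__ = ["UNetSpec", "UNet", "TDMLayer", "build_unet", "compute_tdm", "apply_tdm", "infer"]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyperparameters of the U-net."""

    depth: int = 4
    base_kernels: int = 8
    conv_kernel_size: int = 3
    pool_stride: int = 2
    convs_per_block: int = 2
    final_block_convs: int = 3  # convs_per_block 3x3 convs + linear 1x1 output

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_kernels < 1:
            raise ValueError("depth and base_kernels must be >= 1")
        if self.pool_stride != 2:
            raise ValueError("only pool stride 2 is supported")
        if self.final_block_convs != self.convs_per_block + 1:
            raise ValueError("final block must be convs_per_block 3x3 convs plus a 1x1 conv")

    @property
    def encoder_kernels(self) -> list[int]:
        """Kernel counts per encoder level, plus the bottleneck."""
        return [self.base_kernels * 2**level for level in range(self.depth + 1)]


class UNet:
    """Fully convolutional U-net; NHWC float32 in, same-shape single channel out."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator):
        self.spec = spec
        k = spec.conv_kernel_size
        base = spec.base_kernels

        def block(c_in: int, c_out: int) -> list:
            layers = []
            for i in range(spec.convs_per_block):
                layers.append(Conv2D(c_in if i == 0 else c_out, c_out, k, rng))
                layers.append(ReLU())
            return layers

        self.enc_blocks: list[list] = []
        c_prev = 1
        for level in range(spec.depth):
            c = base * 2**level
            self.enc_blocks.append(block(c_prev, c))
            c_prev = c
        self.pools = [MaxPool2() for _ in range(spec.depth)]
        self.bottleneck = block(c_prev, base * 2**spec.depth)
        self.ups = [Upsample2() for _ in range(spec.depth)]
        self.dec_blocks: list[list] = []
        c_prev = base * 2**spec.depth
        for level in reversed(range(spec.depth)):
            c = base * 2**level
            self.dec_blocks.append(block(c_prev + c, c))
            c_prev = c
        self.out_conv = Conv2D(base, 1, 1, rng)
        self._concat_splits: list[int] = []

    # -- parameters --------------------------------------------------------

    def _convs(self) -> list[Conv2D]:
        convs = []
        for blk in self.enc_blocks + [self.bottleneck] + self.dec_blocks:
            convs.extend(layer for layer in blk if isinstance(layer, Conv2D))
        convs.append(self.out_conv)
        return convs

    def params(self) -> list[Param]:
        out: list[Param] = []
        for conv in self._convs():
            out.extend(conv.params)
        return out

    @property
    def n_params(self) -> int:
        return sum(conv.n_params for conv in self._convs())

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v

    def copy(self) -> "UNet":
        return copy.deepcopy(self)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != 1:
            raise ValueError("input must be NHWC with one channel")
        div = 2**self.spec.depth
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(
                f"input side must be divisible by 2^depth = {div}, got {x.shape[1:3]}"
            )
        h = np.ascontiguousarray(x, dtype=DTYPE)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                h = layer.forward(h)
            skips.append(h)
            h = pool.forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        self._concat_splits = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            self._concat_splits.append(h.shape[3])
            h = np.concatenate([h, skip], axis=3)
            for layer in blk:
                h = layer.forward(h)
        return self.out_conv.forward(h)

    def backward(self, dy: np.ndarray) -> None:
        g = self.out_conv.backward(np.ascontiguousarray(dy, dtype=DTYPE))
        dskips: list[np.ndarray] = []
        for up, blk, split in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(self._concat_splits)
        ):
            for layer in reversed(blk):
                g = layer.backward(g)
            dskips.append(g[..., split:])
            g = up.backward(np.ascontiguousarray(g[..., :split]))
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # dskips was collected shallowest level first; the encoder backward
        # walks deepest level first, so pair them reversed
        for blk, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            g = pool.backward(g) + dskip
            for layer in reversed(blk):
                g = layer.backward(g)


def build_unet(spec: UNetSpec = UNetSpec(), seed: int = 0) -> UNet:
    """Build a U-net with Glorot-uniform weights and zero biases."""
    return UNet(spec, np.random.default_rng(seed))


@dataclass
class TDMLayer:
    """Non-trainable positive multiplicative map applied to the U-net output."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("TDM values must be a 2D map")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("TDM values must be finite and > 0")


def _values(x) -> np.ndarray:
    return np.asarray(x.values if hasattr(x, "values") else x, dtype=np.float64)


def compute_tdm(ppd_cal, inferred_cal, eps_fraction: float = 0.01) -> TDMLayer:
    """TDM from the large open calibration beam.

    ``values = ppd / inferred`` wherever the stage-1 inference exceeds
    ``eps_fraction`` of its own maximum, and 1.0 elsewhere.  Both maps must
    already be edge-corrected and on one grid.
    """
    ppd = _values(ppd_cal)
    inf = _values(inferred_cal)
    if ppd.shape != inf.shape:
        raise ValueError("calibration maps must share one grid")
    guard = inf > eps_fraction * inf.max()
    if np.any(ppd[guard] <= 0):
        raise ValueError("non-positive reference dose inside the guarded region")
    values = np.ones_like(ppd)
    values[guard] = ppd[guard] / inf[guard]
    return TDMLayer(values=values, provenance="260 mm open square calibration beam")


def apply_tdm(net_output: np.ndarray, tdm: TDMLayer) -> np.ndarray:
    """Hadamard product of the network output with the frozen TDM map.

    Accepts a 2D map or an NHWC batch; gradients flow to the network only
    (the TDM holds no :class:`~portaldose.nn.Param`).
    """
    out = np.asarray(net_output)
    if out.ndim == 2:
        if out.shape != tdm.values.shape:
            raise ValueError(f"shape mismatch: {out.shape} vs {tdm.values.shape}")
        return out * tdm.values
    if out.ndim == 4:
        if out.shape[1:3] != tdm.values.shape:
            raise ValueError(f"shape mismatch: {out.shape[1:3]} vs {tdm.values.shape}")
        return out * tdm.values.astype(out.dtype)[None, :, :, None]
    raise ValueError("net output must be 2D or NHWC")


def infer(
    network: UNet,
    tdm: TDMLayer | None,
    mpi: PortalImage,
    norm: NormalizationFactors,
    crop_px: int | None = None,
) -> DoseDistribution:
    """Convert one portal image to an absolute dose plane (Gy).

    Pipeline: edge correction -> input normalization -> single U-net forward
    pass -> optional TDM Hadamard product -> absolute dose calibration.
    """
    grid = mpi.grid
    if tdm is not None and tdm.values.shape != (grid.n_pixels, grid.n_pixels):
        raise ValueError("TDM grid does not match the portal image grid")
    cp = default_crop_px(grid) if crop_px is None else crop_px
    x = normalize(edge_correct(mpi.values.astype(np.float64), cp), norm.input_factor)
    out = network.forward(x[None, :, :, None].astype(DTYPE))[0, :, :, 0].astype(np.float64)
    if tdm is not None:
        out = apply_tdm(out, tdm)
    return calibrate(out, norm.output_factor, grid)
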
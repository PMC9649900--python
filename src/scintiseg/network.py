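"""The recurrent dilated-residual/inception segmentation network.

The feature extractor stacks dilated residual convolution blocks with
pooling, an inception bottleneck, and an upsampling decoder, and is run
recurrently: at step t the output feature map is

    z(t) = W_F * u(t) + W_R * x(t-1) + b,      x(0) = 0,

with W_F the feedforward and W_R the recurrent convolution (applied to the
previous step's activated state) and the same weights shared across steps,
so unrolling adds no parameters.  A 1x1 head maps the final state to
per-pixel lesion logits; the membership map is the logistic of the logits.

Dilated convolution arithmetic: with kernel k and dilation d the effective
kernel is n = k + (k-1)(d-1) and the output size o = floor((i + 2p - n)/s) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import LesionMask, MaskSource
from .nn import (BatchNorm2d, Conv2d, MaxPool2d, Module, PReLU, Sequential,
                 Tensor, UpsampleBilinear2x, concat, conv2d)

__all__ = ["ConvSpec", "ModelConfig", "SoftSegmentation", "conv_output_size",
           "DilatedResidualBlock", "InceptionBlock", "recurrent_step",
           "RecurrentSegmenter", "build_model"]


@dataclass
class ConvSpec:
    """Geometry of a (possibly dilated) convolution layer."""

    kernel: int = 3
    dilation: int = 1
    padding: int = 0
    stride: int = 1
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.kernel < 1 or self.dilation < 1 or self.stride < 1 or self.padding < 0:
            raise ValueError(f"invalid convolution spec: {self}")

    @property
    def effective_kernel(self) -> int:
        return self.kernel + (self.kernel - 1) * (self.dilation - 1)


def conv_output_size(i: int, spec: ConvSpec) -> int:
    """Output size o = floor((i + 2p - n)/s) + 1 with n the effective kernel."""
    n = spec.effective_kernel
    o = (i + 2 * spec.padding - n) // spec.stride + 1
    if o < 1:
        raise ValueError(
            f"input size {i} too small for effective kernel {n} "
            f"with padding {spec.padding}")
    return o


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``stage_channels``: widths of the encoder stages; the last entry is the
    inception bottleneck output width, the first is also the recurrent state
    width.  Spatial size halves between consecutive stages (pooling after
    each dilated-residual stage, stride-2 branches inside the inception
    block), and the decoder restores full resolution.
    """

    recurrence_t: int = 3
    stage_channels: list[int] = field(default_factory=lambda: [16, 32, 64, 128])
    dilation: int = 2
    share_recurrent_weights: bool = True
    input_size: int = 256
    use_dilated: bool = True      # ablation: dilation=1 when off
    use_inception: bool = True    # ablation: plain strided conv bottleneck
    use_residual: bool = True     # ablation: drop the skip path
    seed: int = 0

    def __post_init__(self):
        if self.recurrence_t < 1:
            raise ValueError("recurrence_t must be >= 1")
        if len(self.stage_channels) < 2:
            raise ValueError("need at least one encoder stage plus a bottleneck")


@dataclass
class SoftSegmentation:
    """Per-pixel lesion membership in [0, 1] with its binarization."""

    membership: np.ndarray
    logits: np.ndarray
    threshold: float = 0.5

    @property
    def mask(self) -> LesionMask:
        return LesionMask((self.membership > self.threshold).astype(np.uint8),
                          source=MaskSource.PREDICTED)


class DilatedResidualBlock(Module):
    """Two-path block: DilatedConv-BN-PReLU twice, plus a 1x1 skip path.

    The output is the elementwise sum of the two paths; spatial size is
    preserved by padding each dilated convolution to "same".
    """

    def __init__(self, in_ch: int, out_ch: int, dilation: int = 2,
                 residual: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        pad = dilation  # same-padding for k=3: p = d
        self.conv1 = Conv2d(in_ch, out_ch, 3, dilation=dilation, padding=pad, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.act1 = PReLU(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, dilation=dilation, padding=pad, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.act2 = PReLU(out_ch)
        self.residual = residual
        self.skip = Conv2d(in_ch, out_ch, 1, rng=rng) if residual else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.act1(self.bn1(self.conv1(x)))
        h = self.act2(self.bn2(self.conv2(h)))
        if self.residual:
            return h + self.skip(x)
        return h


class InceptionBlock(Module):
    """Multi-kernel block that halves the grid resolution.

    Five parallel branches — factorized 1x3/3x1, factorized 1x7/7x1, 1x1,
    5x5, and 1x1 -> 2x2 max pooling — each ending with stride 2; the outputs
    are depth-concatenated.
    """

    def __init__(self, in_ch: int, out_ch: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if out_ch < 5:
            raise ValueError("inception block needs at least 5 output channels")
        w = out_ch // 5
        widths = [w, w, w, w, out_ch - 4 * w]
        self.b13 = Sequential(
            Conv2d(in_ch, widths[0], (1, 3), padding=(0, 1), rng=rng),
            Conv2d(widths[0], widths[0], (3, 1), stride=(2, 2),
                   padding=(1, 0), rng=rng))
        self.b17 = Sequential(
            Conv2d(in_ch, widths[1], (1, 7), padding=(0, 3), rng=rng),
            Conv2d(widths[1], widths[1], (7, 1), stride=(2, 2),
                   padding=(3, 0), rng=rng))
        self.b11 = Conv2d(in_ch, widths[2], 1, stride=2, rng=rng)
        self.b55 = Conv2d(in_ch, widths[3], 5, stride=2, padding=2, rng=rng)
        self.bpool = Sequential(Conv2d(in_ch, widths[4], 1, rng=rng), MaxPool2d())
        self.bn = BatchNorm2d(out_ch)
        self.act = PReLU(out_ch)
        self.out_channels = out_ch

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] % 2 or x.shape[-2] % 2:
            raise ValueError(
                f"inception block needs even spatial size, got {x.shape[-2:]}")
        branches = [self.b13(x), self.b17(x), self.b11(x), self.b55(x),
                    self.bpool(x)]
        return self.act(self.bn(concat(branches, axis=1)))


def recurrent_step(u: Tensor, x_prev: Tensor, w_f: Tensor, w_r: Tensor,
                   b: Tensor, padding: int = 0) -> Tensor:
    """One recurrence update: z = W_F * u + W_R * x_prev + b (convolutions)."""
    z = conv2d(u, w_f, b, padding=padding) + conv2d(x_prev, w_r, None,
                                                    padding=padding)
    return z


class _RecurrentCell(Module):
    """Holds W_F, W_R, b for one recurrence step (k=3, same padding).

    The feedforward input carries one extra channel — the raw input image
    (a long skip from the network input) — so the recurrence sees count
    intensity directly alongside the extracted features.
    """

    def __init__(self, n_ch: int, rng: np.random.Generator, extra_in: int = 1):
        super().__init__()
        scale = np.sqrt(2.0 / ((n_ch + extra_in) * 9))
        self.w_f = Tensor(rng.normal(0, scale, (n_ch, n_ch + extra_in, 3, 3)),
                          requires_grad=True)
        self.w_r = Tensor(rng.normal(0, scale * 0.5, (n_ch, n_ch, 3, 3)),
                          requires_grad=True)
        self.b = Tensor(np.zeros(n_ch), requires_grad=True)

    def forward(self, u: Tensor, x_prev: Tensor) -> Tensor:
        return recurrent_step(u, x_prev, self.w_f, self.w_r, self.b, padding=1)

    def drive(self, u: Tensor) -> Tensor:
        """The feedforward half W_F * u + b (constant across unroll steps)."""
        return conv2d(u, self.w_f, self.b, padding=1)

    def recur(self, drive: Tensor, x_prev: Tensor) -> Tensor:
        return drive + conv2d(x_prev, self.w_r, None, padding=1)


class RecurrentSegmenter(Module):
    """Encoder -> inception bottleneck -> decoder, unrolled recurrently."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.stage_channels
        dilation = cfg.dilation if cfg.use_dilated else 1

        stages = [DilatedResidualBlock(1, ch[0], dilation=dilation,
                                       residual=cfg.use_residual, rng=rng)]
        for i in range(1, len(ch) - 1):
            stages.append(MaxPool2d())
            stages.append(DilatedResidualBlock(ch[i - 1], ch[i], dilation=dilation,
                                               residual=cfg.use_residual, rng=rng))
        self.encoder = Sequential(*stages)
        if cfg.use_inception:
            self.bottleneck = InceptionBlock(ch[-2], ch[-1], rng=rng)
        else:
            self.bottleneck = Sequential(
                Conv2d(ch[-2], ch[-1], 3, stride=2, padding=1, rng=rng),
                BatchNorm2d(ch[-1]), PReLU(ch[-1]))

        dec = []
        for i in range(len(ch) - 1, 0, -1):
            # reduce channels with a 1x1 conv before upsampling, then refine
            dec.append(Conv2d(ch[i], ch[i - 1], 1, rng=rng))
            dec.append(UpsampleBilinear2x())
            dec.append(Conv2d(ch[i - 1], ch[i - 1], 3, padding=1, rng=rng))
            dec.append(BatchNorm2d(ch[i - 1]))
            dec.append(PReLU(ch[i - 1]))
        self.decoder = Sequential(*dec)

        n_state = ch[0]
        if cfg.share_recurrent_weights:
            self.cells = [_RecurrentCell(n_state, rng)]
        else:
            self.cells = [_RecurrentCell(n_state, rng)
                          for _ in range(cfg.recurrence_t)]
        self.state_act = PReLU(n_state)
        self.head = Conv2d(n_state, 1, 1, rng=rng)

    def forward(self, x: Tensor, t: int | None = None) -> Tensor:
        """Full-resolution lesion logits for an NCHW batch."""
        cfg = self.config
        t = cfg.recurrence_t if t is None else t
        if t < 1:
            raise ValueError("recurrence t must be >= 1")
        if not cfg.share_recurrent_weights and t > len(self.cells):
            raise ValueError(
                f"model built with {len(self.cells)} unshared recurrent cells; "
                f"cannot unroll t={t}")
        if x.ndim != 4:
            raise ValueError(f"expected NCHW input, got shape {x.shape}")
        # the feedforward drive: the extractor applied to the (constant)
        # image, with the image itself appended as a long skip channel
        features = self.decoder(self.bottleneck(self.encoder(x)))
        u = concat([features, x], axis=1)
        state = Tensor(np.zeros((x.shape[0], self.config.stage_channels[0])
                                + x.shape[2:], dtype=features.data.dtype))
        drive = None
        for step in range(t):
            cell = self.cells[0] if cfg.share_recurrent_weights else self.cells[step]
            if drive is None or not cfg.share_recurrent_weights:
                # the feedforward input u is the same every step, so its
                # convolution is computed once when weights are shared
                drive = cell.drive(u)
            state = self.state_act(cell.recur(drive, state))
        return self.head(state)

    def segment(self, image: np.ndarray, t: int | None = None,
                threshold: float = 0.5,
                bright_positive: bool = True) -> SoftSegmentation:
        """Run the model in eval mode on one normalized 2-D image.

        The two-phase region energy is invariant under swapping the inside
        and outside labels, so a model trained without (enough) manual
        labels may converge with inverted polarity.  Lesions are by
        definition the high-uptake class; with ``bright_positive`` (the
        default) the membership map is flipped when the predicted inside
        is darker on average than the outside.
        """
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {image.shape}")
        was_training = self.training
        self.eval()
        logits = self.forward(Tensor(image[None, None]), t=t).data[0, 0]
        if was_training:
            self.train()
        logits = logits.astype(np.float64)
        membership = 1.0 / (1.0 + np.exp(-np.clip(logits, -60.0, 60.0)))
        if bright_positive:
            pred = membership > threshold
            if pred.any() and (~pred).any() and (
                    image[pred].mean() < image[~pred].mean()):
                membership, logits = 1.0 - membership, -logits
        return SoftSegmentation(membership=membership, logits=logits,
                                threshold=threshold)


def build_model(config: ModelConfig | None = None) -> RecurrentSegmenter:
    return RecurrentSegmenter(config)
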
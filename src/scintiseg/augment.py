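"""Training-set enlargement: geometric transforms and a DCGAN generator.

Geometric augmentation applies flips, small rotations and translations
identically to each image and its lesion mask (label transport), recording
provenance so that augmented copies keep their source's patient grouping
key.  The adversarial route trains a small deep-convolutional GAN — the
generator G maps latent z ~ P_Z to fake images, the discriminator D is
trained k times per generator step (k = 3 by default) on the minimax value

    E_x[log D(x)] + E_z[log(1 - D(G(z)))].

GAN samples carry no lesion masks and enter training only through the
unsupervised loss branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .annotation import LesionMask
from .nn import (Adam, BatchNorm2d, Conv2d, LeakyReLU, Linear, Module,
                 Sequential, Sigmoid, Tensor, UpsampleBilinear2x, relu)
from .scan_io import CountMatrix

__all__ = ["GeometricTransform", "GanConfig", "apply_transform",
           "augment_dataset", "default_recipe", "AugmentedSample",
           "gan_value", "DcganGenerator", "DcganDiscriminator",
           "train_dcgan", "generate_gan_samples", "GanResult"]


@dataclass
class GeometricTransform:
    """A label-preserving spatial transform."""

    kind: str                      # hflip | vflip | rotate | translate
    angle_deg: float = 0.0         # rotate
    shift: tuple[float, float] = (0.0, 0.0)  # translate: (dx, dy) pixels

    def describe(self) -> str:
        if self.kind == "rotate":
            return f"rotate{self.angle_deg:+g}"
        if self.kind == "translate":
            return f"translate{self.shift[0]:+g}_{self.shift[1]:+g}"
        return self.kind


def apply_transform(m: CountMatrix, mask: LesionMask, t: GeometricTransform
                    ) -> tuple[CountMatrix, LesionMask]:
    """Apply the same spatial map to image (bilinear) and mask (nearest).

    Integer translations are exact index shifts; rotation uses bilinear
    interpolation for counts (rounded back to integers) and nearest
    neighbour for the mask.  Out-of-canvas regions are zero-filled.
    """
    img = m.counts.astype(np.float64)
    msk = mask.mask
    h, w = img.shape
    if t.kind == "hflip":
        img2, msk2 = img[:, ::-1], msk[:, ::-1]
    elif t.kind == "vflip":
        img2, msk2 = img[::-1, :], msk[::-1, :]
    elif t.kind == "rotate":
        img2 = ndi.rotate(img, t.angle_deg, reshape=False, order=1,
                          mode="constant", cval=0.0)
        msk2 = ndi.rotate(msk, t.angle_deg, reshape=False, order=0,
                          mode="constant", cval=0)
    elif t.kind == "translate":
        dx, dy = t.shift
        if abs(dx) >= w or abs(dy) >= h:
            raise ValueError(f"translation {t.shift} larger than image {w}x{h}")
        if dx == int(dx) and dy == int(dy):
            img2 = _int_shift(img, int(dy), int(dx))
            msk2 = _int_shift(msk, int(dy), int(dx))
        else:
            img2 = ndi.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)
            msk2 = ndi.shift(msk, (dy, dx), order=0, mode="constant", cval=0)
    else:
        raise ValueError(f"unknown transform kind {t.kind!r}")
    img2 = np.clip(np.round(img2), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return (CountMatrix(img2, view=m.view, pixel_size_mm=m.pixel_size_mm),
            LesionMask((np.asarray(msk2) > 0).astype(np.uint8), source=mask.source))


def _int_shift(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(a)
    ys = slice(max(dy, 0), a.shape[0] + min(dy, 0))
    xs = slice(max(dx, 0), a.shape[1] + min(dx, 0))
    ys_src = slice(max(-dy, 0), a.shape[0] + min(-dy, 0))
    xs_src = slice(max(-dx, 0), a.shape[1] + min(-dx, 0))
    out[ys, xs] = a[ys_src, xs_src]
    return out


def default_recipe() -> list[list[GeometricTransform]]:
    """~19 composite variants per source: {flip} x {rotation} x {translation}.

    2 flips x 5 rotations x 2 translations minus the identity = 19; with the
    original kept alongside, 112 sources yield 2240 samples, matching the
    scale of a 112 -> ~2280 augmentation.
    """
    variants = []
    for flip in (False, True):
        for angle in (-10.0, -5.0, 0.0, 5.0, 10.0):
            for shift in ((0.0, 0.0), (8.0, 0.0)):
                steps: list[GeometricTransform] = []
                if flip:
                    steps.append(GeometricTransform("hflip"))
                if angle:
                    steps.append(GeometricTransform("rotate", angle_deg=angle))
                if shift != (0.0, 0.0):
                    steps.append(GeometricTransform("translate", shift=shift))
                if steps:
                    variants.append(steps)
    return variants


@dataclass
class AugmentedSample:
    sample_id: str
    image: CountMatrix
    mask: LesionMask | None
    patient_key: str
    source_id: str | None = None          # None for originals
    transform: str | None = None
    provenance: str = "original"          # original | geometric | gan


def augment_dataset(samples: list[AugmentedSample],
                    recipe: list[list[GeometricTransform]] | None,
                    seed: int = 0) -> list[AugmentedSample]:
    """Originals plus one transformed copy per (source, recipe variant).

    Every augmented sample records its source id and transform chain and
    inherits its source's patient key, so grouped train/test splits keep a
    patient's variants together.
    """
    if not samples:
        raise ValueError("augment_dataset needs a non-empty input")
    if not recipe:
        return list(samples)
    out = list(samples)
    for s in samples:
        for variant in recipe:
            img, msk = s.image, s.mask if s.mask is not None else LesionMask(
                np.zeros(s.image.counts.shape, dtype=np.uint8))
            for t in variant:
                img, msk = apply_transform(img, msk, t)
            desc = "+".join(t.describe() for t in variant)
            out.append(AugmentedSample(
                sample_id=f"{s.sample_id}~{desc}",
                image=img, mask=None if s.mask is None else msk,
                patient_key=s.patient_key, source_id=s.sample_id,
                transform=desc, provenance="geometric"))
    return out


# -- DCGAN ----------------------------------------------------------------------

@dataclass
class GanConfig:
    latent_dim: int = 32
    iterations_k: int = 3       # discriminator steps per generator step
    image_size: int = 64
    base_channels: int = 16
    lr: float = 2e-4
    batch_size: int = 16
    steps: int = 200            # generator steps
    seed: int = 0

    def __post_init__(self):
        if self.iterations_k < 1:
            raise ValueError("iterations_k must be >= 1")
        if self.image_size % 8:
            raise ValueError("image_size must be divisible by 8")


def gan_value(d_real: np.ndarray, d_fake: np.ndarray,
              eps: float = 1e-12) -> float:
    """The minimax objective E[log D(x)] + E[log(1 - D(G(z)))]."""
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty probability batch")
    d_real = np.clip(d_real, eps, 1 - eps)
    d_fake = np.clip(d_fake, eps, 1 - eps)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


class DcganGenerator(Module):
    """latent z -> dense 4x4 seed -> three upsample+conv blocks -> sigmoid."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.base_channels
        self.seed_size = cfg.image_size // 8
        self.seed_ch = c * 4
        self.fc = Linear(cfg.latent_dim, self.seed_ch * self.seed_size ** 2, rng=rng)
        self.blocks = Sequential(
            UpsampleBilinear2x(), Conv2d(c * 4, c * 2, 3, padding=1, rng=rng),
            BatchNorm2d(c * 2), LeakyReLU(0.2),
            UpsampleBilinear2x(), Conv2d(c * 2, c, 3, padding=1, rng=rng),
            BatchNorm2d(c), LeakyReLU(0.2),
            UpsampleBilinear2x(), Conv2d(c, 1, 3, padding=1, rng=rng),
            Sigmoid())
        self.latent_dim = cfg.latent_dim

    def forward(self, z: Tensor) -> Tensor:
        h = relu(self.fc(z))
        h = h.reshape(z.shape[0], self.seed_ch, self.seed_size, self.seed_size)
        return self.blocks(h)


class DcganDiscriminator(Module):
    """Three stride-2 conv blocks -> dense -> probability."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.base_channels
        self.blocks = Sequential(
            Conv2d(1, c, 3, stride=2, padding=1, rng=rng), LeakyReLU(0.2),
            Conv2d(c, c * 2, 3, stride=2, padding=1, rng=rng),
            BatchNorm2d(c * 2), LeakyReLU(0.2),
            Conv2d(c * 2, c * 4, 3, stride=2, padding=1, rng=rng),
            BatchNorm2d(c * 4), LeakyReLU(0.2))
        flat = (cfg.image_size // 8) ** 2 * c * 4
        self.fc = Linear(flat, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.blocks(x)
        h = h.reshape(h.shape[0], -1)
        return self.fc(h).sigmoid()


@dataclass
class GanResult:
    generator: DcganGenerator
    discriminator: DcganDiscriminator
    history: list[dict] = field(default_factory=list)
    config: GanConfig = field(default_factory=GanConfig)


def _bce(p: Tensor, target: float, eps: float = 1e-7) -> Tensor:
    p = p.clip(eps, 1 - eps)
    if target == 1.0:
        return -(p.log().mean())
    return -((1.0 - p).log().mean())


def train_dcgan(real_images: np.ndarray, cfg: GanConfig | None = None) -> GanResult:
    """Alternating minimax training: k discriminator steps per generator step.

    ``real_images``: (N, H, W) floats in [0, 1], all the same size.  Fully
    seeded, so the loss history is reproducible run to run on CPU.
    """
    cfg = cfg or GanConfig()
    real = np.asarray(real_images, dtype=np.float64)
    if real.ndim != 3:
        raise ValueError(f"expected (N, H, W) images, got shape {real.shape}")
    if real.shape[1] != cfg.image_size or real.shape[2] != cfg.image_size:
        raise ValueError(
            f"images are {real.shape[1]}x{real.shape[2]}, config says "
            f"{cfg.image_size}")
    rng = np.random.default_rng(cfg.seed)
    gen = DcganGenerator(cfg, np.random.default_rng(rng.integers(2 ** 31)))
    disc = DcganDiscriminator(cfg, np.random.default_rng(rng.integers(2 ** 31)))
    opt_g = Adam(gen.parameters(), lr=cfg.lr, beta1=0.5)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, beta1=0.5)
    history: list[dict] = []
    bs = min(cfg.batch_size, len(real))
    for step in range(cfg.steps):
        for _ in range(cfg.iterations_k):
            idx = rng.choice(len(real), size=bs, replace=False)
            x = Tensor(real[idx][:, None])
            z = Tensor(rng.standard_normal((bs, cfg.latent_dim)))
            fake = gen(z).detach()
            d_real = disc(x)
            d_fake = disc(fake)
            loss_d = _bce(d_real, 1.0) + _bce(d_fake, 0.0)
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()
            history.append({
                "step": step, "phase": "discriminator",
                "loss": loss_d.item(),
                "value": gan_value(d_real.data, d_fake.data),
            })
        z = Tensor(rng.standard_normal((bs, cfg.latent_dim)))
        d_on_fake = disc(gen(z))
        loss_g = _bce(d_on_fake, 1.0)  # non-saturating generator objective
        opt_g.zero_grad()
        loss_g.backward()
        opt_g.step()
        history.append({"step": step, "phase": "generator",
                        "loss": loss_g.item()})
        if not math.isfinite(history[-1]["loss"]):
            raise FloatingPointError(f"GAN diverged at step {step}")
    return GanResult(generator=gen, discriminator=disc, history=history,
                     config=cfg)


def generate_gan_samples(generator: DcganGenerator, n: int,
                         seed: int = 0) -> np.ndarray:
    """Draw ``n`` images from the generator; values in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    generator.eval()
    out = []
    for start in range(0, n, 32):
        bs = min(32, n - start)
        z = Tensor(rng.standard_normal((bs, generator.latent_dim)))
        out.append(generator(z).data[:, 0])
    generator.train()
    return np.concatenate(out, axis=0)
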
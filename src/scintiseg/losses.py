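"""The semi-supervised segmentation loss and the pixel-wise metrics.

The loss combines an unsupervised Chan–Vese-style region energy, applied to
every sample, with a label-guided term applied only to the labeled subset:

    l = l_U + alpha * l_S                                  (alpha = 0.4)

    l_U = v * Area(inside) + sum_in |g - c1|^2 + sum_out |g - c2|^2
    l_S = TV(f(g)) + sum_Omega ((1 - mu)^2 - (0 - mu)^2) * f(g)
        = TV(f(g)) + sum_Omega (1 - 2*mu) * f(g)

with g the normalized image, f(g) the per-pixel lesion membership, c1/c2
the mean intensity inside/outside the curve, mu the binary manual label
(background 0), v = 0.004 the area weight, and TV the anisotropic total
variation (forward differences; replicate boundary, i.e. border differences
vanish).  The crisp set sums of the original energy are relaxed with soft
membership weights m and (1 - m) so the loss is differentiable end-to-end;
feeding a hard 0/1 membership recovers the crisp energy exactly.

All functions accept either numpy arrays or autodiff ``Tensor`` inputs, and
sum over the trailing two (spatial) axes per image, so batched (N, 1, H, W)
maps work unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import LesionMask
from .nn.autodiff import Tensor, tabs, tsum

__all__ = ["LossComponents", "RegionStatistics", "region_statistics",
           "unsupervised_loss", "supervised_loss", "total_loss", "total_variation",
           "confusion_counts", "metrics", "SegMetrics", "fit_membership",
           "DEFAULT_ALPHA", "DEFAULT_AREA_WEIGHT"]

DEFAULT_ALPHA = 0.4
DEFAULT_AREA_WEIGHT = 0.004
_EPS = 1e-30  # guards empty-region means; exactly 0 when the region is empty


@dataclass
class LossComponents:
    """The (l_U, l_S, l) bundle for one sample or batch."""

    l_u: float
    l_s: float
    l_total: float
    alpha: float = DEFAULT_ALPHA
    v: float = DEFAULT_AREA_WEIGHT
    background_label_value: int = 0

    def __post_init__(self):
        if not np.isfinite([self.l_u, self.l_s, self.l_total]).all():
            raise FloatingPointError(f"non-finite loss components: {self}")


@dataclass
class RegionStatistics:
    c1: float        # mean intensity inside the curve
    c2: float        # mean intensity outside the curve
    area_inside: float  # soft pixel count


def _spatial_axes(x) -> tuple[int, int]:
    nd = x.ndim
    return (nd - 2, nd - 1)


def _region_terms(g, m):
    """Soft region means c1, c2 and the inside area, per image.

    Keeps spatial dims so the result broadcasts against (…, H, W).  Empty
    regions yield a mean of exactly 0 (the denominator guard only matters
    at soft mass ~1e-30, far below any pixel count).
    """
    ax = _spatial_axes(m)
    area = tsum(m, axis=ax, keepdims=True)
    outside = tsum(1.0 - m, axis=ax, keepdims=True)
    c1 = tsum(m * g, axis=ax, keepdims=True) / (area + _EPS)
    c2 = tsum((1.0 - m) * g, axis=ax, keepdims=True) / (outside + _EPS)
    return c1, c2, area


def region_statistics(g: np.ndarray, m: np.ndarray) -> RegionStatistics:
    """Mean intensities inside/outside a (soft) membership map for one image."""
    g, m = np.asarray(g, float), np.asarray(m, float)
    if g.shape != m.shape:
        raise ValueError(f"shape mismatch: image {g.shape} vs membership {m.shape}")
    c1, c2, area = _region_terms(g, m)
    return RegionStatistics(c1=float(c1.squeeze()), c2=float(c2.squeeze()),
                            area_inside=float(area.squeeze()))


def unsupervised_loss(g, m, v: float = DEFAULT_AREA_WEIGHT):
    """Chan–Vese region energy with soft membership (summed over the batch)."""
    c1, c2, _ = _region_terms(g, m)
    area_term = v * tsum(m)
    fit_in = tsum(m * (g - c1) ** 2)
    fit_out = tsum((1.0 - m) * (g - c2) ** 2)
    return area_term + fit_in + fit_out


def total_variation(m):
    """Anisotropic TV, forward differences, replicate boundary."""
    nd = m.ndim
    down = [slice(None)] * nd
    up = [slice(None)] * nd
    down[nd - 2], up[nd - 2] = slice(1, None), slice(None, -1)
    tv = tsum(tabs(m[tuple(down)] - m[tuple(up)]))
    down[nd - 2] = up[nd - 2] = slice(None)
    down[nd - 1], up[nd - 1] = slice(1, None), slice(None, -1)
    return tv + tsum(tabs(m[tuple(down)] - m[tuple(up)]))


def supervised_loss(m, mu):
    """Label-guided smoothness + region term.

    ``mu`` is the binary per-pixel manual label (background 0).  The region
    term sums (1 - 2*mu) * m: it rewards membership on lesion pixels and
    penalizes it on background.
    """
    mu_arr = mu.mask if isinstance(mu, LesionMask) else np.asarray(mu)
    if not np.isin(mu_arr, (0, 1)).all():
        raise ValueError("label mask must be binary")
    mu_arr = mu_arr.astype(np.float64)
    return total_variation(m) + tsum((1.0 - 2.0 * mu_arr) * m)


def total_loss(g: np.ndarray, m, mu=None,
               alpha: float = DEFAULT_ALPHA,
               v: float = DEFAULT_AREA_WEIGHT) -> LossComponents:
    """Combine the unsupervised and (for labeled samples) supervised losses.

    ``mu=None`` marks an unlabeled sample: l = l_U, with l_S recorded as 0.
    """
    l_u = unsupervised_loss(g, m, v=v)
    l_u = l_u.item() if isinstance(l_u, Tensor) else float(l_u)
    if mu is None:
        return LossComponents(l_u=l_u, l_s=0.0, l_total=l_u, alpha=alpha, v=v)
    l_s = supervised_loss(m, mu)
    l_s = l_s.item() if isinstance(l_s, Tensor) else float(l_s)
    return LossComponents(l_u=l_u, l_s=l_s, l_total=l_u + alpha * l_s,
                          alpha=alpha, v=v)


# -- evaluation metrics ---------------------------------------------------------

def confusion_counts(pred: LesionMask | np.ndarray,
                     truth: LesionMask | np.ndarray) -> tuple[int, int, int, int]:
    """Pixel-wise (TP, FP, FN, TN) with lesion as the positive class."""
    p = (pred.mask if isinstance(pred, LesionMask) else np.asarray(pred)).astype(bool)
    t = (truth.mask if isinstance(truth, LesionMask) else np.asarray(truth)).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    return tp, fp, fn, tn


@dataclass
class SegMetrics:
    dsc: float
    cpa: float | None     # precision; None when the prediction is empty
    recall: float | None  # None when the truth is empty


def metrics(tp: int, fp: int, fn: int) -> SegMetrics:
    """DSC = 2TP/(FP+2TP+FN); CPA = TP/(TP+FP); Recall = TP/(TP+FN).

    Conventions: DSC of two empty masks is 1; CPA/Recall with a zero
    denominator are reported as None and excluded from averages.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("negative confusion counts")
    denom = fp + 2 * tp + fn
    dsc = 1.0 if denom == 0 else 2.0 * tp / denom
    cpa = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return SegMetrics(dsc=dsc, cpa=cpa, recall=recall)


# -- direct Chan–Vese optimisation ---------------------------------------------

def fit_membership(g: np.ndarray, v: float = DEFAULT_AREA_WEIGHT,
                   iters: int = 500, lr: float = 0.25,
                   ) -> tuple[np.ndarray, list[float]]:
    """Minimize l_U directly over a per-pixel membership map (no network).

    The membership is parameterized as a sigmoid of logits optimized with
    Adam; logits are initialized proportional to the centered image so the
    two-phase symmetry of the energy is broken.  Returns the final
    membership map and the loss history.
    """
    from .nn.optim import Adam

    g = np.asarray(g, dtype=np.float64)
    init = 4.0 * (g - g.mean())
    logits = Tensor(init, requires_grad=True)
    opt = Adam([logits], lr=lr)
    history: list[float] = []
    for _ in range(iters):
        opt.zero_grad()
        m = logits.sigmoid()
        loss = unsupervised_loss(Tensor(g), m, v=v) * (1.0 / g.size)
        loss.backward()
        opt.step()
        history.append(loss.item() * g.size)
    return 1.0 / (1.0 + np.exp(-logits.data)), history
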
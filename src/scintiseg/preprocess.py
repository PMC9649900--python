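"""Preprocessing: thorax cropping, dual-view aggregation, normalisation.

A whole-body bone scan is acquired as an anterior and a posterior view.  The
two views are fused by horizontally mirroring the posterior view and adding
it pixel-wise to the anterior view, so that a lesion visible in either view
is present in the aggregated image.  The thoracic region (the most common
metastasis site) is extracted with a three-step heuristic: whole body ->
body area -> upper body -> thoracic window, emitted as an exactly 256x256
(configurable) crop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scan_io import CountMatrix, View

__all__ = ["DualViewScan", "CropRegions", "CropConfig", "crop_thorax",
           "aggregate_views", "mirror", "normalize_for_network"]


@dataclass
class DualViewScan:
    """Paired anterior/posterior count matrices for one patient acquisition."""

    anterior: CountMatrix
    posterior: CountMatrix
    patient_id: str = ""

    def __post_init__(self):
        if self.anterior.counts.shape != self.posterior.counts.shape:
            raise ValueError(
                f"view shapes differ: anterior {self.anterior.counts.shape} "
                f"vs posterior {self.posterior.counts.shape}")


@dataclass
class CropRegions:
    """The three nested boxes of the cropping decomposition.

    Boxes are half-open rectangles (x0, y0, x1, y1) in source-image pixels.
    """

    body_box: tuple[int, int, int, int]
    upper_body_box: tuple[int, int, int, int]
    thorax_box: tuple[int, int, int, int]

    def validate(self, height: int, width: int) -> None:
        def inside(inner, outer):
            return (outer[0] <= inner[0] and outer[1] <= inner[1]
                    and inner[2] <= outer[2] and inner[3] <= outer[3])

        img = (0, 0, width, height)
        if not (inside(self.thorax_box, self.upper_body_box)
                and inside(self.upper_body_box, self.body_box)
                and inside(self.body_box, img)):
            raise ValueError(f"crop boxes are not nested: {self}")


@dataclass
class CropConfig:
    noise_threshold: int = 0      # counts; pixels above it belong to the body
    margin: int = 0               # pixels added around the body bounding box
    upper_fraction: float = 0.45  # top share of body height = upper body
    head_fraction: float = 0.12   # head/shoulder line as share of body height
    out_size: int = 256


def _bounding_box(mask: np.ndarray, margin: int, height: int, width: int):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("no body region detected (image has no counts above "
                         "the noise threshold)")
    y0 = max(int(rows[0]) - margin, 0)
    y1 = min(int(rows[-1]) + 1 + margin, height)
    x0 = max(int(cols[0]) - margin, 0)
    x1 = min(int(cols[-1]) + 1 + margin, width)
    return x0, y0, x1, y1


def crop_thorax(m: CountMatrix, config: CropConfig | None = None
                ) -> tuple[CountMatrix, CropRegions]:
    """Extract the thoracic window from a whole-body scan.

    Three steps: (1) body box = bounding box of pixels above the noise
    threshold plus a small margin; (2) upper body = top ``upper_fraction`` of
    the body box; (3) thorax = ``out_size``-row window starting below the
    head/shoulder line (``head_fraction`` of body height), width-centered on
    the body, zero-padded to ``out_size`` x ``out_size``.
    """
    cfg = config or CropConfig()
    h, w = m.counts.shape
    body = _bounding_box(m.counts > cfg.noise_threshold, cfg.margin, h, w)
    bx0, by0, bx1, by1 = body
    body_h = by1 - by0

    ub_y1 = by0 + max(int(round(cfg.upper_fraction * body_h)), 1)
    ub_y1 = min(max(ub_y1, by0 + 1), by1)
    upper = (bx0, by0, bx1, ub_y1)

    ty0 = by0 + int(round(cfg.head_fraction * body_h))
    ty0 = min(max(ty0, by0), ub_y1 - 1)
    ty1 = min(ty0 + cfg.out_size, ub_y1)

    cx = (bx0 + bx1) // 2
    tx0 = max(cx - cfg.out_size // 2, bx0)
    tx1 = min(tx0 + cfg.out_size, bx1)
    thorax = (tx0, ty0, tx1, ty1)

    regions = CropRegions(body_box=body, upper_body_box=upper, thorax_box=thorax)
    regions.validate(h, w)

    out = np.zeros((cfg.out_size, cfg.out_size), dtype=m.counts.dtype)
    crop = m.counts[ty0:ty1, tx0:tx1]
    # center the (possibly narrower) source window in the padded output
    oy = (cfg.out_size - crop.shape[0]) // 2
    ox = (cfg.out_size - crop.shape[1]) // 2
    out[oy:oy + crop.shape[0], ox:ox + crop.shape[1]] = crop
    return CountMatrix(out, view=m.view, pixel_size_mm=m.pixel_size_mm), regions


def mirror(m: CountMatrix) -> CountMatrix:
    """Horizontal flip (columns reversed, rows unchanged)."""
    return CountMatrix(m.counts[:, ::-1].copy(), view=m.view,
                       pixel_size_mm=m.pixel_size_mm)


def aggregate_views(scan: DualViewScan) -> CountMatrix:
    """Pixel-wise addition of the anterior view and the mirrored posterior view.

    ``out[i, j] = anterior[i, j] + posterior[i, W-1-j]``.
    """
    a, p = scan.anterior, scan.posterior
    if a.counts.shape != p.counts.shape:
        raise ValueError("anterior and posterior dimensions differ")
    summed = a.counts.astype(np.uint32) + mirror(p).counts.astype(np.uint32)
    return CountMatrix(summed, view=View.AGGREGATED, pixel_size_mm=a.pixel_size_mm)


def normalize_for_network(m: CountMatrix, strategy: str = "max",
                          clip_max: float = 65535.0,
                          percentile: float = 99.5) -> np.ndarray:
    """Map integer counts to a float image in [0, 1] for the network.

    Strategies:
      * ``"max"`` (default): counts / c_max; an all-zero image maps to zeros.
        Invariant under integer rescaling of the counts.
      * ``"clip"``: counts clipped to [0, clip_max] then divided by clip_max.
      * ``"percentile"``: counts clipped at the given percentile, then scaled.
    """
    c = m.counts.astype(np.float64)
    if strategy == "max":
        cmax = c.max()
        return c / cmax if cmax > 0 else c
    if strategy == "clip":
        return np.clip(c, 0, clip_max) / clip_max
    if strategy == "percentile":
        hi = np.percentile(c, percentile)
        return np.clip(c, 0, hi) / hi if hi > 0 else c
    raise ValueError(f"unknown normalisation strategy {strategy!r}")
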
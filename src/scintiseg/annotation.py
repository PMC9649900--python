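"""Polygon rasterization, inter-annotator agreement, consensus ground truth.

Each image is labeled independently by three physicians.  For every lesion,
the pairwise area difference

    dA = 1 - |A1 n A2| / |A1 u A2|        (1 - IoU of the rasterized masks)

is computed between the three closed curves; if the largest pairwise dA does
not exceed the threshold t_dA (5% by default), one of the three labels is
selected uniformly at random as the ground truth, otherwise the triplet is
rejected and a new annotation round is required (the caller's loop).

dA is evaluated on rasterized masks — the downstream loss and metrics are
pixel-based — with a pixel counted as inside when its center lies inside or
on the polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import shapely

from .scan_io import AnnotationSet, PolygonLabel

__all__ = ["MaskSource", "LesionMask", "AgreementResult", "ConsensusOutcome",
           "polygon_to_mask", "area_difference", "consensus_select",
           "DEFAULT_AGREEMENT_THRESHOLD"]

DEFAULT_AGREEMENT_THRESHOLD = 0.05


class MaskSource(str, Enum):
    MANUAL = "manual"
    PREDICTED = "predicted"
    SYNTHETIC_TRUTH = "synthetic-truth"


@dataclass
class LesionMask:
    """Binary per-pixel lesion map (1 = lesion, 0 = background)."""

    mask: np.ndarray
    source: MaskSource = MaskSource.MANUAL

    def __post_init__(self):
        a = np.asarray(self.mask)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.mask = a.astype(np.uint8)
        self.source = MaskSource(self.source)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class AgreementResult:
    """Pairwise agreement of a three-annotator label triplet for one lesion."""

    pairwise_delta: tuple[float, float, float]
    accepted: bool
    chosen_annotator: str | None
    threshold: float = DEFAULT_AGREEMENT_THRESHOLD


@dataclass
class ConsensusOutcome:
    per_lesion: dict[str, AgreementResult] = field(default_factory=dict)
    masks: dict[str, LesionMask] = field(default_factory=dict)
    labels: dict[str, PolygonLabel] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return all(r.accepted for r in self.per_lesion.values())

    def combined_mask(self, height: int, width: int) -> LesionMask:
        out = np.zeros((height, width), dtype=np.uint8)
        for m in self.masks.values():
            out |= m.mask
        return LesionMask(out, source=MaskSource.MANUAL)


def polygon_to_mask(label: PolygonLabel, height: int, width: int) -> LesionMask:
    """Rasterize a closed polygon: pixel set iff its center is inside or on it."""
    label.check_bounds(height, width)
    poly = shapely.Polygon(label.points)
    if poly.area == 0:
        raise ValueError(f"degenerate polygon {label.lesion_id!r} has zero area")
    xs, ys = np.meshgrid(np.arange(width, dtype=float),
                         np.arange(height, dtype=float))
    # intersects == inside or on the boundary
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    return LesionMask(inside.reshape(height, width).astype(np.uint8),
                      source=MaskSource.MANUAL)


def area_difference(l1: PolygonLabel, l2: PolygonLabel,
                    height: int, width: int) -> float:
    """Pairwise area difference dA = 1 - IoU of the rasterized masks."""
    m1 = polygon_to_mask(l1, height, width).mask.astype(bool)
    m2 = polygon_to_mask(l2, height, width).mask.astype(bool)
    union = int(np.logical_or(m1, m2).sum())
    if union == 0:
        raise ValueError("both masks are empty; IoU undefined")
    inter = int(np.logical_and(m1, m2).sum())
    return 1.0 - inter / union


def consensus_select(aset: AnnotationSet, height: int, width: int,
                     t_delta_a: float = DEFAULT_AGREEMENT_THRESHOLD,
                     seed: int = 0) -> ConsensusOutcome:
    """Run the three-annotator agreement gate and pick the ground truth.

    Requires exactly three annotators; lesions correspond across annotators
    by ``lesion_id``.  Per lesion, all three pairwise dA values are computed;
    if their maximum is <= ``t_delta_a`` one annotator's label is chosen
    uniformly at random (reproducibly, from ``seed``), otherwise the lesion
    is marked not accepted.
    """
    annotators = aset.annotators
    if len(annotators) != 3:
        raise ValueError(
            f"consensus protocol requires exactly 3 annotators, got {len(annotators)}")
    by_lesion: dict[str, dict[str, PolygonLabel]] = {}
    for ann in annotators:
        for label in aset.labels_by_annotator[ann]:
            by_lesion.setdefault(label.lesion_id, {})[ann] = label
    rng = np.random.default_rng(seed)
    outcome = ConsensusOutcome()
    for lesion_id in sorted(by_lesion):
        labels = by_lesion[lesion_id]
        if sorted(labels) != annotators:
            missing = sorted(set(annotators) - set(labels))
            raise ValueError(
                f"lesion {lesion_id!r} missing annotations from {missing}")
        pairs = [(annotators[0], annotators[1]),
                 (annotators[0], annotators[2]),
                 (annotators[1], annotators[2])]
        deltas = tuple(area_difference(labels[a], labels[b], height, width)
                       for a, b in pairs)
        accepted = max(deltas) <= t_delta_a
        chosen = None
        if accepted:
            chosen = annotators[int(rng.integers(3))]
            outcome.labels[lesion_id] = labels[chosen]
            outcome.masks[lesion_id] = polygon_to_mask(labels[chosen],
                                                       height, width)
        outcome.per_lesion[lesion_id] = AgreementResult(
            pairwise_delta=deltas, accepted=accepted,
            chosen_annotator=chosen, threshold=t_delta_a)
    return outcome
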
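"""Dataset splitting, semi-supervised training, evaluation, delineation.

The split is patient-grouped: all samples sharing a patient key (including
augmented copies of one source) land on the same side of the 70/30
train/test boundary.  Training minimizes the combined loss — the
unsupervised region energy on every sample plus alpha times the supervised
term on the labeled subset — with Adam (learning rate 5e-4, momentum 0.9,
weight decay 1e-4 by default).  Evaluation runs the trained model
repeatedly (10 runs by default) on the test subset and averages the
pixel-wise DSC/CPA/Recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .annotation import LesionMask
from .losses import (DEFAULT_ALPHA, DEFAULT_AREA_WEIGHT, SegMetrics,
                     confusion_counts, metrics, supervised_loss,
                     unsupervised_loss)
from .network import ModelConfig, RecurrentSegmenter, SoftSegmentation
from .nn import Adam, Tensor
from .scan_io import PolygonLabel

__all__ = ["TrainConfig", "SplitPlan", "TrainSample", "make_split",
           "train_semisupervised", "evaluate_repeated", "EvalResult",
           "extract_lesion_boundaries", "run_ablation", "desk_model_config"]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 5e-4
    momentum: float = 0.9          # Adam beta1
    weight_decay: float = 1e-4
    epochs: int = 400
    batch_size: int = 10
    input_size: int = 256
    label_fraction: float = 0.37
    alpha: float = DEFAULT_ALPHA
    area_weight: float = DEFAULT_AREA_WEIGHT
    recurrence_t: int | None = None  # None: the model's configured default
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must be in [0, 1]")


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    labeled_train_ids: list[str]
    grouping_key: dict[str, str]   # sample id -> patient key

    def validate(self) -> None:
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValueError("train and test sets overlap")
        if not set(self.labeled_train_ids) <= train:
            raise ValueError("labeled ids must be a subset of the train ids")
        train_patients = {self.grouping_key[i] for i in self.train_ids}
        test_patients = {self.grouping_key[i] for i in self.test_ids}
        straddling = train_patients & test_patients
        if straddling:
            raise ValueError(f"patients straddle the split: {sorted(straddling)}")


@dataclass
class TrainSample:
    """One training record: normalized image and (optionally) its label."""

    sample_id: str
    image: np.ndarray              # float in [0, 1]
    mask: np.ndarray | None        # binary, or None for unlabeled
    patient_key: str = ""


def make_split(manifest: list[tuple[str, str, bool]] | list[TrainSample],
               train_fraction: float = 0.7, label_fraction: float = 0.37,
               seed: int = 0) -> SplitPlan:
    """Patient-grouped train/test split with a seeded labeled subset.

    ``manifest`` is either a list of (sample_id, patient_key, has_label)
    triples or a list of :class:`TrainSample`.  Whole patients are assigned
    to the training side until the train share is nearest ``train_fraction``;
    the labeled subset is drawn uniformly from train samples that possess
    labels.
    """
    entries: list[tuple[str, str, bool]] = []
    for e in manifest:
        if isinstance(e, TrainSample):
            entries.append((e.sample_id, e.patient_key, e.mask is not None))
        else:
            entries.append(tuple(e))
    if not entries:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[str]] = {}
    for sid, patient, _ in entries:
        by_patient.setdefault(patient, []).append(sid)
    patients = sorted(by_patient)
    rng.shuffle(patients)
    total = len(entries)
    target = train_fraction * total
    train_ids: list[str] = []
    for p in patients:
        cur = len(train_ids)
        nxt = cur + len(by_patient[p])
        # stop once adding this patient moves the share away from the target
        if cur > 0 and abs(nxt - target) > abs(cur - target):
            break
        train_ids.extend(by_patient[p])
    train_set = set(train_ids)
    test_ids = [sid for sid, _, _ in entries if sid not in train_set]
    has_label = {sid for sid, _, lab in entries if lab}
    candidates = sorted(sid for sid in train_ids if sid in has_label)
    n_labeled = int(round(label_fraction * len(train_ids)))
    n_labeled = min(n_labeled, len(candidates))
    labeled = (sorted(rng.choice(candidates, size=n_labeled, replace=False))
               if n_labeled else [])
    plan = SplitPlan(train_ids=sorted(train_ids), test_ids=sorted(test_ids),
                     labeled_train_ids=list(labeled),
                     grouping_key={sid: pk for sid, pk, _ in entries})
    plan.validate()
    return plan


def _batch_loss(model: RecurrentSegmenter, images: np.ndarray,
                masks: list[np.ndarray | None], cfg: TrainConfig) -> Tensor:
    """Mean per-pixel combined loss over one mixed batch."""
    n, h, w = images.shape
    logits = model(Tensor(images[:, None]), t=cfg.recurrence_t)
    m = logits.sigmoid()
    g = images[:, None]
    loss = unsupervised_loss(g, m, v=cfg.area_weight) * (1.0 / (n * h * w))
    labeled = [i for i, msk in enumerate(masks) if msk is not None]
    if labeled and cfg.alpha > 0:
        mu = np.stack([masks[i] for i in labeled])[:, None]
        m_lab = m[np.asarray(labeled)]
        l_s = supervised_loss(m_lab, mu) * (1.0 / (len(labeled) * h * w))
        loss = loss + cfg.alpha * l_s
    return loss


def train_semisupervised(model: RecurrentSegmenter, data: list[TrainSample],
                         split: SplitPlan, cfg: TrainConfig | None = None,
                         ) -> tuple[RecurrentSegmenter, list[dict]]:
    """Train with the combined loss; returns the model and per-epoch history.

    Batches mix labeled and unlabeled samples; the supervised branch applies
    only to batch members whose id is in ``split.labeled_train_ids``.
    Aborts with a diagnostic if the loss becomes non-finite.
    """
    cfg = cfg or TrainConfig()
    split.validate()
    by_id = {s.sample_id: s for s in data}
    labeled_ids = set(split.labeled_train_ids)
    train = [by_id[i] for i in split.train_ids]
    if not train:
        raise ValueError("empty training set")
    if cfg.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    opt = Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.momentum,
               weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(train), cfg.batch_size):
            batch = [train[i] for i in order[start:start + cfg.batch_size]]
            images = np.stack([s.image for s in batch])
            masks = [s.mask if s.sample_id in labeled_ids else None
                     for s in batch]
            loss = _batch_loss(model, images, masks, cfg)
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={value}); "
                    f"batch ids: {[s.sample_id for s in batch]}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "n_labeled": len(labeled_ids)})
    model.eval()
    return model, history


@dataclass
class EvalResult:
    mean: dict[str, float]
    sd: dict[str, float]
    per_run: list[dict[str, float]] = field(default_factory=list)
    per_image: list[SegMetrics] = field(default_factory=list)


def _evaluate_once(model: RecurrentSegmenter, test: list[TrainSample],
                   t: int | None = None) -> tuple[dict[str, float], list[SegMetrics]]:
    per_image: list[SegMetrics] = []
    for s in test:
        if s.mask is None:
            raise ValueError(f"test sample {s.sample_id} has no ground truth")
        seg = model.segment(s.image, t=t)
        tp, fp, fn, _ = confusion_counts(seg.mask, s.mask)
        per_image.append(metrics(tp, fp, fn))
    summary = {}
    for key in ("dsc", "cpa", "recall"):
        vals = [getattr(m, key) for m in per_image if getattr(m, key) is not None]
        summary[key] = float(np.mean(vals)) if vals else float("nan")
    return summary, per_image


def evaluate_repeated(model: RecurrentSegmenter, test: list[TrainSample],
                      runs: int = 10, t: int | None = None) -> EvalResult:
    """Evaluate ``runs`` times and average (the repeated-runs protocol).

    The model is deterministic at evaluation time, so the runs coincide and
    the sd is zero — they are still executed and reported, since the
    protocol averages whatever randomness evaluation might carry.
    """
    if not test:
        raise ValueError("empty test set")
    per_run: list[dict[str, float]] = []
    per_image_last: list[SegMetrics] = []
    for _ in range(runs):
        summary, per_image_last = _evaluate_once(model, test, t=t)
        per_run.append(summary)
    mean = {k: float(np.mean([r[k] for r in per_run])) for k in per_run[0]}
    sd = {k: float(np.std([r[k] for r in per_run])) for k in per_run[0]}
    return EvalResult(mean=mean, sd=sd, per_run=per_run,
                      per_image=per_image_last)


def extract_lesion_boundaries(seg: SoftSegmentation | LesionMask,
                              min_area: int = 4) -> list[PolygonLabel]:
    """Closed boundary polygons of the 8-connected lesion components.

    Components smaller than ``min_area`` pixels are suppressed.  Each
    remaining component yields one closed iso-contour polygon (sub-pixel,
    marching squares at the 0.5 level) in (x, y) pixel coordinates.
    """
    mask = seg.mask.mask if isinstance(seg, SoftSegmentation) else seg.mask
    labeled = measure.label(mask, connectivity=2)
    polygons: list[PolygonLabel] = []
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        component = np.pad((labeled == region.label).astype(float), 1)
        contours = measure.find_contours(component, 0.5)
        contour = max(contours, key=len)  # outer boundary
        pts = np.column_stack([contour[:, 1] - 1, contour[:, 0] - 1])  # (x, y)
        polygons.append(PolygonLabel(points=pts,
                                     lesion_id=f"lesion{region.label}",
                                     annotator_id="predicted"))
    return polygons


def desk_model_config(image_size: int = 64, **overrides) -> ModelConfig:
    """The small CPU-friendly model profile used for phantom experiments."""
    defaults = dict(stage_channels=[3, 6, 12], input_size=image_size,
                    recurrence_t=3)
    defaults.update(overrides)
    return ModelConfig(**defaults)


def run_ablation(data: list[TrainSample], split: SplitPlan,
                 cfg: TrainConfig, cases: dict[str, dict] | None = None,
                 seeds: tuple[int, ...] = (0, 1, 2),
                 image_size: int = 64) -> list[dict]:
    """Train model variants on the same splits and tabulate the metrics.

    Default cases sweep the feature-extractor components from a plain
    convolutional baseline (1#) to the full dilated + inception + residual
    model (4#).
    """
    if cases is None:
        cases = {
            "1#": dict(use_dilated=False, use_inception=False, use_residual=False),
            "2#": dict(use_dilated=True, use_inception=False, use_residual=False),
            "3#": dict(use_dilated=True, use_inception=True, use_residual=False),
            "4#": dict(use_dilated=True, use_inception=True, use_residual=True),
        }
    by_id = {s.sample_id: s for s in data}
    test = [by_id[i] for i in split.test_ids]
    table: list[dict] = []
    for name, flags in cases.items():
        per_seed = {"dsc": [], "cpa": [], "recall": []}
        for seed in seeds:
            model_cfg = desk_model_config(image_size=image_size, seed=seed,
                                          **flags)
            model = RecurrentSegmenter(model_cfg)
            run_cfg = TrainConfig(**{**cfg.__dict__, "seed": seed})
            model, _ = train_semisupervised(model, data, split, run_cfg)
            result = evaluate_repeated(model, test, runs=1)
            for k in per_seed:
                per_seed[k].append(result.mean[k])
        row = {"case": name, **flags, "n_seeds": len(seeds)}
        for k, vals in per_seed.items():
            row[f"{k}_mean"] = float(np.mean(vals))
            row[f"{k}_sd"] = float(np.std(vals))
        table.append(row)
    return table
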
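"""I/O for bone-scan count matrices and polygon lesion annotations.

A planar bone scan is a 2-D grid of radiotracer detection counts, each pixel
a 16-bit unsigned integer (whole-body scans are 256x1024 at 2.26 mm/pixel;
cropped thoracic regions are 256x256).  Counts are deliberately *never*
rescaled at I/O time — the dynamic range varies too much between patients for
a fixed normalisation, so normalisation is an explicit preprocessing step.

On-disk formats:

* 16-bit grayscale PNG (canonical), optionally with a JSON metadata sidecar
  ``<stem>.meta.json`` holding ``{"view": ..., "pixel_size_mm": ...}``;
* raw little-endian uint16 matrix (``.raw``) with a mandatory sidecar
  ``<stem>.json`` holding ``{"height", "width", "view", "pixel_size_mm"}``;
* single-frame DICOM (read-only, requires ``pydicom``);
* LabelMe-style JSON ("shapes" with "label"/"points"/"shape_type") for
  polygon lesion annotations, with annotators kept in separate files or in a
  top-level "annotator" field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "View", "CountMatrix", "PolygonLabel", "AnnotationSet",
    "ScanFormatError", "read_scan", "write_scan",
    "read_labelme", "write_labelme",
]

DEFAULT_PIXEL_SIZE_MM = 2.26


class View(str, Enum):
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"
    AGGREGATED = "aggregated"
    UNKNOWN = "unknown"


class ScanFormatError(ValueError):
    """A file violates the 16-bit non-negative count-matrix contract."""


@dataclass
class CountMatrix:
    """A 2-D grid of non-negative integer radiotracer counts."""

    counts: np.ndarray
    view: View = View.UNKNOWN
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self):
        a = np.asarray(self.counts)
        if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
            raise ScanFormatError(f"counts must be a 2-D grid, got shape {a.shape}")
        if np.issubdtype(a.dtype, np.floating):
            if not np.all(a == np.round(a)):
                raise ScanFormatError("counts must be integers")
            a = a.astype(np.int64)
        if a.min() < 0:
            raise ScanFormatError("counts must be non-negative")
        self.counts = a.astype(np.uint32)
        self.view = View(self.view)

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def c_max(self) -> int:
        return int(self.counts.max())


@dataclass
class PolygonLabel:
    """A closed curve l = <p1, ..., pm = p1> delineating one lesion.

    Points are (x, y) in pixel units, origin top-left, x = column, y = row,
    0-based with pixel centers at integer coordinates (LabelMe convention).
    """

    points: np.ndarray
    lesion_id: str = "lesion"
    annotator_id: str = "unknown"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (m, 2), got {pts.shape}")
        if not np.allclose(pts[0], pts[-1]):
            pts = np.vstack([pts, pts[0]])  # close the curve
        if len(np.unique(np.round(pts[:-1], 9), axis=0)) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def check_bounds(self, height: int, width: int) -> None:
        x, y = self.points[:, 0], self.points[:, 1]
        if (x.min() < -0.5 or y.min() < -0.5
                or x.max() > width - 0.5 or y.max() > height - 0.5):
            raise ValueError(
                f"polygon exceeds image bounds {width}x{height}: "
                f"x in [{x.min():.2f}, {x.max():.2f}], "
                f"y in [{y.min():.2f}, {y.max():.2f}]")


@dataclass
class AnnotationSet:
    """All manual labels for one image, grouped by annotator."""

    image_ref: str = ""
    labels_by_annotator: dict[str, list[PolygonLabel]] = field(default_factory=dict)

    @property
    def annotators(self) -> list[str]:
        return sorted(self.labels_by_annotator)

    def lesion_ids(self) -> list[str]:
        ids: list[str] = []
        for labels in self.labels_by_annotator.values():
            for l in labels:
                if l.lesion_id not in ids:
                    ids.append(l.lesion_id)
        return ids

    @classmethod
    def merge(cls, sets: list["AnnotationSet"]) -> "AnnotationSet":
        out = cls(image_ref=sets[0].image_ref if sets else "")
        for s in sets:
            for ann, labels in s.labels_by_annotator.items():
                out.labels_by_annotator.setdefault(ann, []).extend(labels)
        return out


# -- count-matrix I/O -----------------------------------------------------------

def read_scan(path: str | Path, view: View | str = View.UNKNOWN) -> CountMatrix:
    """Read a count matrix; counts are returned exactly as stored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    pixel_size = DEFAULT_PIXEL_SIZE_MM
    if suffix == ".png":
        with Image.open(path) as im:
            if im.mode not in ("I", "I;16", "I;16B", "L", "P"):
                raise ScanFormatError(
                    f"unsupported PNG mode {im.mode!r}; need <=16-bit grayscale")
            arr = np.asarray(im, dtype=np.int64)
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            view = meta.get("view", view)
            pixel_size = float(meta.get("pixel_size_mm", pixel_size))
    elif suffix == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ScanFormatError(f"raw matrix {path} missing JSON sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        h, w = int(meta["height"]), int(meta["width"])
        arr = np.fromfile(path, dtype="<u2")
        if arr.size != h * w:
            raise ScanFormatError(
                f"raw file holds {arr.size} values, sidecar says {h}x{w}")
        arr = arr.reshape(h, w).astype(np.int64)
        view = meta.get("view", view)
        pixel_size = float(meta.get("pixel_size_mm", pixel_size))
    elif suffix in (".dcm", ".dicom"):
        arr, meta_ps = _read_dicom(path)
        if meta_ps is not None:
            pixel_size = meta_ps
    else:
        raise ScanFormatError(f"unknown scan format {suffix!r}")
    if arr.min() < 0:
        raise ScanFormatError("negative pixel values in stored image")
    if arr.max() > np.iinfo(np.uint16).max:
        raise ScanFormatError(
            f"pixel depth exceeds 16-bit: max value {arr.max()}")
    return CountMatrix(arr.astype(np.uint16), view=View(view),
                       pixel_size_mm=pixel_size)


def _read_dicom(path: Path):
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ScanFormatError("DICOM support requires pydicom") from exc
    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array)
    if arr.ndim != 2:
        raise ScanFormatError(f"DICOM frame is not 2-D (shape {arr.shape})")
    ps = None
    if getattr(ds, "PixelSpacing", None):
        ps = float(ds.PixelSpacing[0])
    return arr.astype(np.int64), ps


def write_scan(m: CountMatrix, path: str | Path) -> None:
    """Write a count matrix so that ``read_scan`` round-trips bit-exactly."""
    path = Path(path)
    if m.counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError(f"count {m.counts.max()} exceeds uint16 range")
    data = m.counts.astype(np.uint16)
    suffix = path.suffix.lower()
    if suffix == ".png":
        Image.fromarray(data.astype(np.int32), mode="I").convert("I;16").save(path)
        meta = {"view": m.view.value, "pixel_size_mm": m.pixel_size_mm}
        path.with_suffix(".meta.json").write_text(json.dumps(meta))
    elif suffix == ".raw":
        data.astype("<u2").tofile(path)
        meta = {"height": m.height, "width": m.width,
                "view": m.view.value, "pixel_size_mm": m.pixel_size_mm}
        path.with_suffix(".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unknown scan format {suffix!r}")


# -- LabelMe polygon I/O --------------------------------------------------------

def read_labelme(path: str | Path) -> AnnotationSet:
    """Parse a LabelMe-dialect JSON file into an :class:`AnnotationSet`.

    Unclosed point lists are closed by appending the first point.  The
    annotator id is taken from a top-level ``"annotator"`` key when present,
    else from the file stem.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    annotator = str(doc.get("annotator", path.stem))
    labels: list[PolygonLabel] = []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type", "polygon") != "polygon":
            continue
        pts = shape["points"]
        if len({(round(float(x), 9), round(float(y), 9)) for x, y in pts}) < 3:
            raise ValueError(
                f"shape {shape.get('label')!r} has fewer than 3 distinct points")
        labels.append(PolygonLabel(points=np.asarray(pts, dtype=np.float64),
                                   lesion_id=str(shape.get("label", "lesion")),
                                   annotator_id=annotator))
    return AnnotationSet(image_ref=str(doc.get("imagePath", "")),
                         labels_by_annotator={annotator: labels} if labels
                         else ({annotator: []} if "annotator" in doc else {}))


def write_labelme(labels: list[PolygonLabel] | AnnotationSet, path: str | Path,
                  image_ref: str = "", annotator: str | None = None) -> None:
    """Write polygons as LabelMe-dialect JSON (one annotator per file)."""
    if isinstance(labels, AnnotationSet):
        aset = labels
        for ann, ls in aset.labels_by_annotator.items():
            if annotator is None or ann == annotator:
                labels = ls
                annotator = ann
                image_ref = image_ref or aset.image_ref
                break
        else:
            labels = []
    doc = {
        "version": "3.0",
        "annotator": annotator or "unknown",
        "imagePath": image_ref,
        "shapes": [
            {"label": l.lesion_id, "shape_type": "polygon",
             "points": [[float(x), float(y)] for x, y in l.points]}
            for l in labels
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
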
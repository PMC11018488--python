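"""Images, point annotations, panicle masks, manifests and patching.

Annotations follow the LabelMe dialect: one JSON document per image with a
``shapes`` list; each flower is a shape of type ``point`` whose single
vertex sits at the convergence point of the filaments.  LabelMe stores
points as (x, y) = (column, row); in memory this package uses 0-based
(row, col) ordering everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class ImageRecord:
    """An RGB image with an identifier.

    ``pixels`` is an H×W×3 uint8 array.
    """

    id: str
    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H×W×3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1×1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass
class PointAnnotationSet:
    """Flower centre points for one image, 0-based (row, col), row-major free order."""

    image_id: str
    points: list[tuple[float, float]]
    image_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.points = [(float(r), float(c)) for r, c in self.points]
        if self.image_shape is not None:
            h, w = self.image_shape
            for idx, (r, c) in enumerate(self.points):
                if not (0 <= r < h and 0 <= c < w):
                    raise ValueError(
                        f"point {idx} at ({r}, {c}) outside image bounds "
                        f"{h}×{w}")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PanicleInstanceMask:
    """Binary foreground mask for one panicle instance; H×W values in {0,1}."""

    image_id: str
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.mask = self.mask.astype(np.uint8)


@dataclass
class ManifestEntry:
    image_path: str
    annotation_path: str
    mask_path: str | None = None
    split: str = "train"


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    seed: int = 0

    def subset(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]

    def save(self, path: str | Path) -> None:
        doc = {"seed": self.seed,
               "entries": [{"image": e.image_path,
                            "annotation": e.annotation_path,
                            "mask": e.mask_path,
                            "split": e.split} for e in self.entries]}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        doc = json.loads(Path(path).read_text())
        entries = [ManifestEntry(d["image"], d["annotation"],
                                 d.get("mask"), d.get("split", "train"))
                   for d in doc["entries"]]
        return cls(entries=entries, seed=int(doc.get("seed", 0)))


# ---------------------------------------------------------------------------
# image / mask files

def read_image(path: str | Path, image_id: str | None = None) -> ImageRecord:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return ImageRecord(image_id or Path(path).stem, arr)


def write_image(image: ImageRecord, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def read_mask(path: str | Path, image_id: str | None = None) -> PanicleInstanceMask:
    """Read a {0,255} PNG mask (any nonzero pixel is foreground)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return PanicleInstanceMask(image_id or Path(path).stem,
                               (arr > 0).astype(np.uint8))


def write_mask(mask: PanicleInstanceMask, path: str | Path) -> None:
    Image.fromarray((mask.mask * 255).astype(np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# LabelMe point annotations

def read_labelme_points(path: str | Path, image_shape: tuple[int, int],
                        label: str | None = None) -> PointAnnotationSet:
    """Read point shapes from a LabelMe JSON file.

    Parameters
    ----------
    image_shape : (H, W) used for bounds validation.
    label : if given, keep only point shapes carrying this label; by
        default all point shapes are read (single-class datasets).
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed LabelMe JSON in {path}: {exc}") from exc
    h, w = image_shape
    points: list[tuple[float, float]] = []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type") != "point":
            continue
        if label is not None and shape.get("label") != label:
            continue
        x, y = shape["points"][0]            # LabelMe stores (x, y)
        points.append((float(y), float(x)))  # -> (row, col)
    for idx, (r, c) in enumerate(points):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(
                f"point {idx} at (row={r}, col={c}) lies outside "
                f"image bounds {h}×{w}")
    return PointAnnotationSet(Path(path).stem, points, (h, w))


def write_labelme_points(annotations: PointAnnotationSet, path: str | Path,
                         image_shape: tuple[int, int] | None = None,
                         label: str = "flower") -> None:
    """Write a PointAnnotationSet as LabelMe-dialect JSON."""
    shape = image_shape or annotations.image_shape
    doc = {
        "version": "5.2.1",
        "flags": {},
        "shapes": [{"label": label,
                    "points": [[c, r]],   # (row,col) -> LabelMe (x,y)
                    "group_id": None,
                    "shape_type": "point",
                    "flags": {}} for r, c in annotations.points],
        "imagePath": f"{annotations.image_id}.png",
        "imageData": None,
        "imageHeight": None if shape is None else int(shape[0]),
        "imageWidth": None if shape is None else int(shape[1]),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# panicle mask application

def apply_panicle_mask(image: ImageRecord, mask: PanicleInstanceMask,
                       pad: int = 0) -> ImageRecord:
    """Zero out background and crop to the mask's padded bounding box.

    Matches the framework's crop stage: the externally segmented panicle
    is isolated on a neutral (zero) background before counting.
    """
    if mask.mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if pad < 0:
        raise ValueError("pad must be ≥ 0")
    m = mask.mask
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size == 0:
        raise ValueError("mask has no foreground pixels (no panicle)")
    r0 = max(int(rows[0]) - pad, 0)
    r1 = min(int(rows[-1]) + 1 + pad, image.height)
    c0 = max(int(cols[0]) - pad, 0)
    c1 = min(int(cols[-1]) + 1 + pad, image.width)
    out = image.pixels * m[:, :, None]
    return ImageRecord(image.id, out[r0:r1, c0:c1])


# ---------------------------------------------------------------------------
# patching and splitting

def _edges(total: int, parts: int) -> list[int]:
    """Cut points for `parts` intervals: floor(total/parts) each, remainder
    absorbed by the last interval."""
    step = total // parts
    edges = [i * step for i in range(parts)] + [total]
    return edges


def split_into_patches(image: ImageRecord, annotations: PointAnnotationSet,
                       grid: tuple[int, int] = (3, 3),
                       ) -> list[tuple[ImageRecord, PointAnnotationSet]]:
    """Tile an image into a rows×cols grid of non-overlapping patches.

    Training uses the default 3×3 grid (9 blocks per sample).  Each point
    belongs to exactly one patch under half-open intervals [lo, hi), with
    coordinates shifted into the patch-local frame.
    """
    gr, gc = grid
    if gr < 1 or gc < 1:
        raise ValueError("grid dims must be ≥ 1")
    if gr > image.height or gc > image.width:
        raise ValueError("grid larger than image")
    re_, ce = _edges(image.height, gr), _edges(image.width, gc)
    out = []
    for i in range(gr):
        for j in range(gc):
            r0, r1, c0, c1 = re_[i], re_[i + 1], ce[j], ce[j + 1]
            pid = f"{image.id}_p{i}{j}"
            pts = [(r - r0, c - c0) for r, c in annotations.points
                   if r0 <= r < r1 and c0 <= c < c1]
            out.append((ImageRecord(pid, image.pixels[r0:r1, c0:c1]),
                        PointAnnotationSet(pid, pts, (r1 - r0, c1 - c0))))
    return out


def split_dataset(manifest: DatasetManifest, train_fraction: float,
                  seed: int) -> DatasetManifest:
    """Deterministic shuffled train/test split.

    The train size is the nearest integer to n·train_fraction, so e.g.
    337 entries at fraction 268/337 give the 268/69 split.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(manifest.entries)
    if n < 2:
        raise ValueError("need at least 2 entries to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    entries = []
    for rank, idx in enumerate(order):
        e = manifest.entries[idx]
        entries.append(ManifestEntry(e.image_path, e.annotation_path,
                                     e.mask_path,
                                     "train" if rank < n_train else "test"))
    # restore manifest order so splits are stable under re-listing
    entries.sort(key=lambda e: [x.image_path for x in manifest.entries]
                 .index(e.image_path))
    return DatasetManifest(entries=entries, seed=seed)


def load_entry(entry: ManifestEntry, root: str | Path = "."
               ) -> tuple[ImageRecord, PointAnnotationSet, PanicleInstanceMask | None]:
    """Load one manifest entry (paths relative to ``root``)."""
    root = Path(root)
    img = read_image(root / entry.image_path)
    ann = read_labelme_points(root / entry.annotation_path, img.shape)
    msk = read_mask(root / entry.mask_path) if entry.mask_path else None
    return img, ann, msk
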
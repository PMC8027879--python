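"""Dataset manifests and image file handling.

A manifest is a table of (image, mask, eyelid side, split) records.
It can be loaded from a CSV file or from a directory pair
(``images/`` + ``masks/`` matched by filename). Masks are binarized on
read (any nonzero pixel becomes 1); color images are converted to
grayscale with a logged warning. Masks and overlays are always written
as PNG so binary labels survive without recompression artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

log = logging.getLogger("meiboseg")

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "imread_gray",
    "imread_mask",
    "imwrite_gray",
    "imwrite_mask",
    "load_dataset",
    "split_dataset",
]


def imread_gray(path) -> np.ndarray:
    """Read an image as 8-bit grayscale; color inputs are converted."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        img = Image.open(path)
    except Exception as exc:  # pragma: no cover - PIL error text varies
        raise ValueError(f"unreadable image {path}: {exc}") from exc
    if img.mode not in ("L", "I;16", "I"):
        log.warning("converting %s from mode %s to grayscale", path.name, img.mode)
        img = img.convert("L")
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def imread_mask(path) -> np.ndarray:
    """Read a mask image, binarizing on read: any nonzero pixel -> 1."""
    return imread_gray(path) > 0


def imwrite_gray(arr, path) -> None:
    Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)


def imwrite_mask(mask, path) -> None:
    Image.fromarray(np.asarray(mask, dtype=bool).astype(np.uint8) * 255).save(path)


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    mask_path: str | None = None
    eyelid_side: str = "upper"
    split: str | None = None


@dataclass
class DatasetManifest:
    """Validated list of dataset records."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def load_images(self) -> list[np.ndarray]:
        return [imread_gray(r.image_path) for r in self.records]

    def load_masks(self) -> list[np.ndarray]:
        return [imread_mask(r.mask_path) for r in self.records if r.mask_path]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_path": r.image_path,
                    "mask_path": r.mask_path or "",
                    "eyelid_side": r.eyelid_side,
                    "split": r.split or "",
                }
                for r in self.records
            ]
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_record(rec: ManifestRecord) -> None:
    if not Path(rec.image_path).is_file():
        raise FileNotFoundError(f"manifest image missing: {rec.image_path}")
    if rec.mask_path:
        if not Path(rec.mask_path).is_file():
            raise FileNotFoundError(f"manifest mask missing: {rec.mask_path}")
        img = imread_gray(rec.image_path)
        mask = imread_mask(rec.mask_path)
        if img.shape != mask.shape:
            raise ValueError(
                f"shape mismatch for {Path(rec.image_path).name}: "
                f"image {img.shape} vs mask {mask.shape}"
            )


def load_dataset(path) -> DatasetManifest:
    """Load and validate a manifest.

    ``path`` is either a CSV with columns image_path[, mask_path,
    eyelid_side, split], or a directory containing ``images/`` and
    optionally ``masks/`` subdirectories matched by file stem.
    """
    path = Path(path)
    records: list[ManifestRecord] = []
    if path.is_dir():
        img_dir = path / "images" if (path / "images").is_dir() else path
        mask_dir = path / "masks" if (path / "masks").is_dir() else None
        for img in sorted(img_dir.glob("*")):
            if img.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            mask = None
            if mask_dir is not None:
                for ext in (".png", ".jpg", ".jpeg"):
                    cand = mask_dir / (img.stem + ext)
                    if cand.is_file():
                        mask = str(cand)
                        break
                if mask is None:
                    raise FileNotFoundError(f"no mask found for image {img.name}")
            records.append(ManifestRecord(str(img), mask))
    elif path.is_file():
        df = pd.read_csv(path)
        if "image_path" not in df.columns:
            raise ValueError("manifest CSV needs an image_path column")
        for _, row in df.iterrows():
            records.append(
                ManifestRecord(
                    image_path=str(row["image_path"]),
                    mask_path=str(row["mask_path"]) if row.get("mask_path") else None,
                    eyelid_side=str(row.get("eyelid_side", "upper") or "upper"),
                    split=str(row["split"]) if row.get("split") else None,
                )
            )
    else:
        raise FileNotFoundError(f"manifest not found: {path}")
    for rec in records:
        _validate_record(rec)
    return DatasetManifest(records)


def split_dataset(
    manifest: DatasetManifest, fractions: dict[str, float], seed: int = 0
) -> DatasetManifest:
    """Seeded random partition of records into named splits.

    Fractions must sum to 1; split sizes are the rounded shares (e.g.
    628 records at 0.8/0.2 give 502 train and 126 validation).
    """
    names = list(fractions)
    fr = np.array([fractions[k] for k in names], dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    n = len(manifest)
    base = np.floor(fr * n).astype(int)
    # hand leftover records to the largest fractional remainders
    for i in np.argsort(-(fr * n - base))[: n - base.sum()]:
        base[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tags = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(names, base):
        tags[order[start : start + size]] = name
        start += size
    return DatasetManifest(
        [replace(r, split=str(tags[i])) for i, r in enumerate(manifest.records)]
    )
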
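"""Collagen-fiber quantification from binary segmentation masks.

Mirrors the study's histology metric: the proportion of tissue area
occupied by collagen fibers,

    proportion (%) = 100 * collagen area / total tissue area,

computed from a pre-segmented binary mask (stain separation and
thresholding are upstream concerns).  An optional tissue mask restricts
the denominator to the sectioned tissue region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SegmentationMask", "collagen_fraction", "load_mask"]


@dataclass(frozen=True)
class SegmentationMask:
    """Binary collagen-positive mask plus optional tissue-region mask."""

    data: np.ndarray
    tissue: np.ndarray | None = None
    pixel_size_um: float | None = None  # not used by the area ratio

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2 or data.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        object.__setattr__(self, "data", data.astype(bool))
        if self.tissue is not None:
            tissue = np.asarray(self.tissue)
            if tissue.shape != data.shape:
                raise ValueError("tissue mask shape must match the collagen mask")
            object.__setattr__(self, "tissue", tissue.astype(bool))


def collagen_fraction(mask: SegmentationMask | np.ndarray, tissue: np.ndarray | None = None) -> float:
    """Collagen proportion in percent of the tissue area."""
    if not isinstance(mask, SegmentationMask):
        mask = SegmentationMask(np.asarray(mask), tissue)
    region = mask.tissue if mask.tissue is not None else np.ones_like(mask.data, dtype=bool)
    n_tissue = int(region.sum())
    if n_tissue == 0:
        raise ValueError("tissue region is empty")
    return 100.0 * int((mask.data & region).sum()) / n_tissue


def load_mask(path: str | Path, tissue_path: str | Path | None = None) -> SegmentationMask:
    """Read a single-channel PNG/TIFF mask; any nonzero pixel is positive."""
    from PIL import Image

    def read(p):
        arr = np.asarray(Image.open(p))
        if arr.ndim == 3:  # collapse channels; any nonzero counts
            arr = arr[..., :3].max(axis=-1)
        return arr > 0

    data = read(path)
    tissue = read(tissue_path) if tissue_path is not None else None
    return SegmentationMask(data, tissue)
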
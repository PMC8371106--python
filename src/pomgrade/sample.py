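"""In-memory image sample container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .grades import GradeLabel


@dataclass
class ImageSample:
    """One RGB raster with its grade label and provenance.

    pixels     : H x W x 3 uint8 array.
    label      : quality grade.
    fruit_id   : which (synthetic) fruit the image depicts.
    view_id    : which camera view of that fruit.
    provenance : "original" or the name of the augmentation that produced it.
    defect_mask: optional H x W bool array marking rendered defect pixels;
                 carried by the synthetic generator for analysis, dropped by
                 augmentation ops that invalidate it geometrically.
    """

    pixels: np.ndarray
    label: GradeLabel
    fruit_id: int
    view_id: int = 0
    provenance: str = "original"
    defect_mask: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        self.pixels = px

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, provenance: str) -> "ImageSample":
        """Derived sample: new raster, same identity, new provenance tag."""
        return replace(self, pixels=pixels, provenance=provenance, defect_mask=None)
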
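"""Topography images: height matrices with physical pixel size.

Heights are in nm.  Images are row-major with row 0 at the TOP of the
field of view, while world coordinates put the origin at the lower-left
with y up; the conversion helpers below are the single source of truth
for that mapping (pixel centers at half-integer offsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .ioutils import atomic_write

__all__ = ["TopographyImage"]


@dataclass
class TopographyImage:
    heights: np.ndarray
    pixel_size: float  # nm / px
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D matrix")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in nm."""
        nr, nc = self.heights.shape
        return nc * self.pixel_size, nr * self.pixel_size

    # -- world <-> pixel ---------------------------------------------------
    def world_to_pixel(self, xy: np.ndarray) -> np.ndarray:
        """Map (x, y) nm to fractional (row, col) pixel coordinates."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        nr = self.heights.shape[0]
        col = xy[:, 0] / self.pixel_size - 0.5
        row = nr - xy[:, 1] / self.pixel_size - 0.5
        return np.column_stack([row, col])

    def pixel_to_world(self, rowcol: np.ndarray) -> np.ndarray:
        """Map fractional (row, col) to (x, y) nm at pixel centers."""
        rowcol = np.atleast_2d(np.asarray(rowcol, dtype=float))
        nr = self.heights.shape[0]
        x = (rowcol[:, 1] + 0.5) * self.pixel_size
        y = (nr - rowcol[:, 0] - 0.5) * self.pixel_size
        return np.column_stack([x, y])

    # -- I/O ---------------------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        with atomic_write(path) as tmp:
            tifffile.imwrite(
                tmp,
                self.heights.astype(np.float32),
                metadata={"pixel_size_nm": self.pixel_size, **self.metadata},
            )

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float | None = None) -> "TopographyImage":
        with tifffile.TiffFile(path) as tif:
            heights = tif.asarray().astype(float)
            meta = {}
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
            elif tif.imagej_metadata:
                meta = dict(tif.imagej_metadata)
        px = pixel_size if pixel_size is not None else float(meta.pop("pixel_size_nm", 0) or 0)
        if px <= 0:
            raise ValueError("pixel size not stored in file; pass pixel_size=")
        meta.pop("shape", None)
        return cls(heights, px, meta)

    def to_text(self, path: str | Path) -> None:
        """Whitespace-delimited matrix with a one-line header comment."""
        with atomic_write(path) as tmp:
            np.savetxt(tmp, self.heights, header=f"pixel_size_nm {self.pixel_size}")

    @classmethod
    def from_text(cls, path: str | Path, pixel_size: float | None = None) -> "TopographyImage":
        px = pixel_size
        if px is None:
            with open(path) as fh:
                first = fh.readline()
            if "pixel_size_nm" in first:
                px = float(first.split()[-1])
        if px is None or px <= 0:
            raise ValueError("pixel size not stored in file; pass pixel_size=")
        return cls(np.loadtxt(path), px)
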
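"""Minimal affine-geotransform support.

Coordinates follow the raster convention: pixel (row, col) with origin at
the top-left corner, world ``x = c + a*col + b*row``, ``y = f + d*col + e*row``
(the same six-coefficient layout used by GDAL/rasterio's ``Affine``).
Map units are assumed to be meters throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeoTransform:
    a: float  # pixel width (x per col)
    b: float  # row rotation
    c: float  # x of the top-left corner
    d: float  # col rotation
    e: float  # pixel height (y per row; negative for north-up)
    f: float  # y of the top-left corner

    def __post_init__(self):
        if self.pixel_area <= 0:
            raise ValueError("geotransform has non-positive pixel area")

    @classmethod
    def north_up(cls, x0: float, y0: float, pixel_size: float) -> "GeoTransform":
        return cls(pixel_size, 0.0, x0, 0.0, -pixel_size, y0)

    @property
    def pixel_area(self) -> float:
        return abs(self.a * self.e - self.b * self.d)

    @property
    def pixel_size(self) -> float:
        """Edge length of a square pixel (sqrt of pixel area)."""
        return float(np.sqrt(self.pixel_area))

    def xy(self, row, col):
        """World coordinates of pixel centers."""
        col = np.asarray(col, dtype=float) + 0.5
        row = np.asarray(row, dtype=float) + 0.5
        return self.c + self.a * col + self.b * row, self.f + self.d * col + self.e * row

    def rowcol(self, x, y):
        """Pixel indices (floor) containing world coordinates."""
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        det = self.a * self.e - self.b * self.d
        col = (self.e * x - self.b * y) / det
        row = (-self.d * x + self.a * y) / det
        return np.floor(row).astype(int), np.floor(col).astype(int)

    def to_list(self):
        return [self.a, self.b, self.c, self.d, self.e, self.f]

    def almost_equals(self, other: "GeoTransform", tol: float = 1e-9) -> bool:
        return all(abs(p - q) <= tol for p, q in zip(self.to_list(), other.to_list()))
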
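"""Segment maps: integer-labeled partitions with per-object statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster_io import Scene


@dataclass
class ObjectStats:
    pixel_count: int
    band_means: dict
    dsm_mean: float
    dsm_sd: float  # population sd over the object's pixels
    bbox: tuple  # (row_min, row_max, col_min, col_max), inclusive


@dataclass
class SegmentMap:
    """Partition of the in-domain pixels into objects (label 0 = outside)."""

    labels: np.ndarray
    object_stats: dict

    def __post_init__(self):
        pos = set(np.unique(self.labels)) - {0}
        if pos != set(self.object_stats):
            raise ValueError("object_stats keys do not match positive labels")

    @property
    def n_objects(self):
        return len(self.object_stats)

    def domain_mask(self):
        return self.labels > 0


def compute_stats(labels: np.ndarray, scene: Scene) -> dict:
    """Per-object pixel counts, band/DSM means, DSM sd and bounding boxes."""
    nlab = int(labels.max()) + 1
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=nlab)
    band_means = {}
    for name, arr in scene.bands.items():
        sums = np.bincount(flat, weights=arr.ravel(), minlength=nlab)
        with np.errstate(invalid="ignore"):
            band_means[name] = sums / counts
    dsm = scene.dsm.ravel()
    dsm_sum = np.bincount(flat, weights=dsm, minlength=nlab)
    dsm_sq = np.bincount(flat, weights=dsm * dsm, minlength=nlab)
    with np.errstate(invalid="ignore"):
        dsm_mean = dsm_sum / counts
        dsm_var = np.maximum(dsm_sq / counts - dsm_mean**2, 0.0)
    slices = ndimage.find_objects(labels)
    stats = {}
    for lab in range(1, nlab):
        if counts[lab] == 0:
            continue
        sl = slices[lab - 1]
        bbox = (sl[0].start, sl[0].stop - 1, sl[1].start, sl[1].stop - 1)
        stats[lab] = ObjectStats(
            pixel_count=int(counts[lab]),
            band_means={b: float(m[lab]) for b, m in band_means.items()},
            dsm_mean=float(dsm_mean[lab]),
            dsm_sd=float(np.sqrt(dsm_var[lab])),
            bbox=bbox,
        )
    return stats
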
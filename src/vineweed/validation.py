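"""Accuracy assessment of the weed/soil classification against ground truth.

The confusion matrix is computed over the pixels whose reference label is
bermudagrass or bare soil (sampling-frame area); reference vine/unknown
pixels are excluded, as are the (rare) pixels the map classed as vine or
nodata inside the frames, which are counted and logged. From the 2x2 area
matrix: overall accuracy OA = 100 * trace / total, producer's accuracy
PA(c) = 100 * diag(c) / reference-total(c) and omission error
OE(c) = 100 - PA(c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .raster_io import CLASS_CODES, LabelRaster
from .segmentation import ClassifiedMap

log = logging.getLogger(__name__)

_EVAL = ("bermudagrass", "bare_soil")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # [reference, classified] pixel counts over _EVAL order
    pixel_area: float

    @property
    def total(self):
        return int(self.counts.sum())

    @property
    def overall_accuracy(self):
        return 100.0 * np.trace(self.counts) / self.counts.sum()

    @property
    def producers_accuracy(self):
        ref_tot = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pa = 100.0 * np.diag(self.counts) / ref_tot
        return dict(zip(_EVAL, pa))

    @property
    def omission_error(self):
        return {c: 100.0 - pa for c, pa in self.producers_accuracy.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"ref_{c}" for c in _EVAL],
                            columns=[f"cls_{c}" for c in _EVAL])

    def report(self) -> dict:
        return {
            "counts_px": self.counts.tolist(),
            "counts_m2": (self.counts * self.pixel_area).tolist(),
            "overall_accuracy_pct": float(self.overall_accuracy),
            "producers_accuracy_pct": {k: float(v) for k, v in self.producers_accuracy.items()},
            "omission_error_pct": {k: float(v) for k, v in self.omission_error.items()},
        }


def confusion_matrix(classified: ClassifiedMap, reference: LabelRaster) -> ConfusionMatrix:
    """2x2 area confusion matrix (bermudagrass, bare_soil) x (classified, reference)."""
    if classified.labels.shape != reference.labels.shape:
        raise ConfigurationError("classified and reference rasters differ in shape")
    ref = reference.labels
    cls = classified.labels
    codes = [CLASS_CODES[c] for c in _EVAL]
    eval_mask = np.isin(ref, codes)
    if not eval_mask.any():
        raise ConfigurationError("no reference bermudagrass/bare_soil pixels to evaluate")
    in_eval_cls = np.isin(cls, codes)
    excluded = int((eval_mask & ~in_eval_cls).sum())
    if excluded:
        log.info("%d frame pixels classified vine/nodata excluded from the matrix", excluded)
    sel = eval_mask & in_eval_cls
    counts = np.zeros((2, 2), dtype=np.int64)
    for i, rc in enumerate(codes):
        for j, cc in enumerate(codes):
            counts[i, j] = int(((ref == rc) & (cls == cc) & sel).sum())
    pixel_area = classified.transform.pixel_area if classified.transform else 1.0
    return ConfusionMatrix(counts=counts, pixel_area=pixel_area)


def holdout_split(labels: LabelRaster, frame_polygons, fraction: float = 0.25,
                  seed: int = 0):
    """Frame-level random split into (analysis, validation) feature lists.

    The analysis side receives ``round-half-up(fraction * n)`` frames; the
    split is at frame (sampling-unit) level, not pixel level, to avoid
    spatial leakage between the spectral analysis and the validation.
    """
    frames = list(frame_polygons)
    if len(frames) < 2:
        raise ConfigurationError("need at least 2 frames to split")
    n_analysis = int(np.floor(fraction * len(frames) + 0.5))
    if n_analysis == 0 or n_analysis == len(frames):
        raise ConfigurationError(
            f"fraction {fraction} leaves an empty side for {len(frames)} frames")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(frames))
    analysis_idx = sorted(order[:n_analysis].tolist())
    validation_idx = sorted(order[n_analysis:].tolist())
    return ([frames[i] for i in analysis_idx], [frames[i] for i in validation_idx])
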
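"""Grapevine classification from DSM height (OBIA phase one).

Chessboard tiles are screened by their within-tile DSM standard deviation:
tiles mixing trellised canopy (~1.5 m) and soil have high relief variance
and become "vine candidates". Candidate tiles (dilated by one tile, so that
canopy interiors wider than a tile are reachable) are then refined at the
pixel level against a local bare-soil reference elevation — a low quantile
of the DSM over non-candidate area in a sliding window — which makes the
classification robust to terrain slope: a pixel is vine iff its height
above the local soil reference exceeds ``height_min``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import ConfigurationError
from .objects import SegmentMap, compute_stats
from .raster_io import Scene

log = logging.getLogger(__name__)

#: defaults for vines on a ~1.5 m vertical trellis vs prostrate (<0.1 m) weeds
DEFAULTS = {"tile_size": 0.5, "dsm_sd_threshold": 0.15,
            "height_min": 0.4, "soil_window": 5.0, "soil_quantile": 0.10}


@dataclass
class VineMask:
    mask: np.ndarray  # boolean, True = vine
    soil_reference: np.ndarray  # local soil elevation (m), finite everywhere


def chessboard_segment(scene: Scene, tile_size: float = DEFAULTS["tile_size"]) -> SegmentMap:
    """Partition the scene into square tiles (edge tiles truncated)."""
    px = scene.transform.pixel_size
    tile_px = int(round(tile_size / px))
    if tile_px < 2:
        raise ConfigurationError(
            f"tile_size {tile_size} m is under 2 pixels at {px} m/px")
    nrow, ncol = scene.shape
    ntc = -(-ncol // tile_px)
    rr = np.arange(nrow) // tile_px
    cc = np.arange(ncol) // tile_px
    labels = (rr[:, None] * ntc + cc[None, :] + 1).astype(np.int32)
    labels[scene.nodata_mask] = 0
    # compact labels so stats keys match the occupied tiles only
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq[0] == 0:
        labels = inv.reshape(labels.shape).astype(np.int32)
    else:
        labels = (inv.reshape(labels.shape) + 1).astype(np.int32)
    return SegmentMap(labels=labels, object_stats=compute_stats(labels, scene))


def detect_vine_candidates(segments: SegmentMap,
                           dsm_sd_threshold: float = DEFAULTS["dsm_sd_threshold"]) -> set:
    """Tiles whose within-tile DSM standard deviation exceeds the threshold."""
    return {lab for lab, s in segments.object_stats.items()
            if s.dsm_sd > dsm_sd_threshold}


def _tile_px(segments: SegmentMap) -> int:
    sizes = [max(s.bbox[1] - s.bbox[0], s.bbox[3] - s.bbox[2]) + 1
             for s in segments.object_stats.values()]
    return int(max(sizes)) if sizes else 1


def local_soil_reference(scene: Scene, exclude_mask: np.ndarray,
                         soil_window: float = DEFAULTS["soil_window"],
                         quantile: float = DEFAULTS["soil_quantile"]) -> np.ndarray:
    """Low-quantile DSM over non-excluded (soil) area, windowed and interpolated.

    The field is partitioned into ``soil_window``-sized windows; within each,
    the given quantile of soil DSM is taken and the window-center values are
    bilinearly interpolated back to the pixel grid, tracking any terrain
    trend. Windows without soil pixels fall back to the nearest window that
    has some (logged).
    """
    px = scene.transform.pixel_size
    w = max(2, int(round(soil_window / px)))
    nrow, ncol = scene.shape
    soil_ok = ~exclude_mask & ~scene.nodata_mask
    nwr, nwc = -(-nrow // w), -(-ncol // w)
    ref = np.full((nwr, nwc), np.nan)
    centers_r = np.empty(nwr)
    centers_c = np.empty(nwc)
    for i in range(nwr):
        r0, r1 = i * w, min((i + 1) * w, nrow)
        centers_r[i] = (r0 + r1 - 1) / 2
        for j in range(nwc):
            c0, c1 = j * w, min((j + 1) * w, ncol)
            sel = soil_ok[r0:r1, c0:c1]
            if sel.any():
                ref[i, j] = np.quantile(scene.dsm[r0:r1, c0:c1][sel], quantile)
    for j in range(nwc):
        c0, c1 = j * w, min((j + 1) * w, ncol)
        centers_c[j] = (c0 + c1 - 1) / 2
    if np.isnan(ref).all():
        raise ConfigurationError("no soil pixels anywhere; cannot build soil reference")
    if np.isnan(ref).any():
        n_empty = int(np.isnan(ref).sum())
        log.warning("%d soil-reference windows had no soil; filled from nearest", n_empty)
        _, (ir, jc) = ndimage.distance_transform_edt(
            np.isnan(ref), return_indices=True)
        ref = ref[ir, jc]
    if nwr == 1 and nwc == 1:
        return np.full((nrow, ncol), ref[0, 0])
    rows = np.arange(nrow)
    cols = np.arange(ncol)
    if nwr == 1:
        interp = np.interp(cols, centers_c, ref[0])
        return np.broadcast_to(interp, (nrow, ncol)).copy()
    if nwc == 1:
        interp = np.interp(rows, centers_r, ref[:, 0])
        return np.broadcast_to(interp[:, None], (nrow, ncol)).copy()
    rgi = RegularGridInterpolator((centers_r, centers_c), ref,
                                  bounds_error=False, fill_value=None)
    rr, cc = np.meshgrid(np.clip(rows, centers_r[0], centers_r[-1]),
                         np.clip(cols, centers_c[0], centers_c[-1]), indexing="ij")
    return rgi(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(nrow, ncol)


def refine_vine_pixels(scene: Scene, candidates: set, segments: SegmentMap,
                       height_min: float = DEFAULTS["height_min"],
                       soil_window: float = DEFAULTS["soil_window"]) -> VineMask:
    """Pixel-level vine classification inside (dilated) candidate tiles."""
    unknown = candidates - set(segments.object_stats)
    if unknown:
        raise ConfigurationError(f"candidate labels not in segmentation: {sorted(unknown)[:5]}")
    cand_mask = np.isin(segments.labels, np.fromiter(candidates, dtype=np.int64)) \
        if candidates else np.zeros(scene.shape, dtype=bool)
    tile = _tile_px(segments)
    eval_mask = ndimage.binary_dilation(cand_mask, structure=np.ones((3, 3), bool),
                                        iterations=tile) if candidates else cand_mask
    soil_ref = local_soil_reference(scene, exclude_mask=cand_mask,
                                    soil_window=soil_window)
    mask = eval_mask & (scene.dsm - soil_ref > height_min) & ~scene.nodata_mask
    return VineMask(mask=mask, soil_reference=soil_ref)


def detect_vines(scene: Scene, tile_size=DEFAULTS["tile_size"],
                 dsm_sd_threshold=DEFAULTS["dsm_sd_threshold"],
                 height_min=DEFAULTS["height_min"],
                 soil_window=DEFAULTS["soil_window"]) -> VineMask:
    """Convenience wrapper running the full phase-one chain."""
    segments = chessboard_segment(scene, tile_size)
    candidates = detect_vine_candidates(segments, dsm_sd_threshold)
    return refine_vine_pixels(scene, candidates, segments, height_min, soil_window)
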
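"""Weed/soil segmentation and classification (OBIA phase two).

The not-vine area is partitioned by bottom-up pairwise region merging in
the Baatz-Schape formulation: the cost of fusing two objects is the
size-weighted increase in heterogeneity,

    f = (1 - shape) * dh_color + shape * dh_shape
    dh_color = sum_b w_b (n_m sd_m,b - n_i sd_i,b - n_j sd_j,b)
    dh_shape = cmpct * (p_m sqrt(n_m) - ...) + (1 - cmpct) * (n_m p_m / pb_m - ...)

with p the object perimeter and pb its bounding-box perimeter (pixel
units). The globally cheapest pair — which is by construction a mutual
best fit — is merged first, and merging continues while f < scale**2.
Object-count equivalence with proprietary implementations is not promised;
the contract is the partition properties and downstream classification
accuracy.

Objects are then classified bermudagrass vs bare soil by an automatic Otsu
threshold on the selected vegetation index, computed over area-weighted
object means (pixel-level mode available), with the vegetation side of the
threshold declared per index in the registry.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import indices as vi
from .errors import ConfigurationError, DegenerateDistributionError
from .geo import GeoTransform
from .objects import SegmentMap, compute_stats
from .raster_io import CLASS_CODES, Scene
from .vine import VineMask

log = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    scale: float = 5.0
    shape: float = 0.3  # weight of shape vs color heterogeneity
    compactness: float = 0.5  # weight of compactness vs smoothness
    band_weights: dict | None = None  # spectral bands default 1; DSM is not used
    seed_block: int | str = "auto"  # pre-aggregation block edge in pixels

    def __post_init__(self):
        if not (0 <= self.shape < 1):
            raise ConfigurationError("shape must be in [0, 1)")
        if not (0 <= self.compactness <= 1):
            raise ConfigurationError("compactness must be in [0, 1]")


@dataclass
class ClassifiedMap:
    """Per-pixel categories {0 nodata, 1 vine, 2 bermudagrass, 3 bare_soil}."""

    labels: np.ndarray
    area_summary: dict
    threshold_used: float
    index_name: str
    transform: GeoTransform | None = None
    crs: str | None = None

    @property
    def shape(self):
        return self.labels.shape


def _auto_block(n_domain: int) -> int:
    if n_domain <= 300_000:
        return 1
    if n_domain <= 5_000_000:
        return 2
    return 4


def _initial_labels(domain_mask: np.ndarray, block: int) -> np.ndarray:
    nrow, ncol = domain_mask.shape
    if block == 1:
        lab = np.zeros((nrow, ncol), dtype=np.int64)
        lab[domain_mask] = np.arange(1, domain_mask.sum() + 1)
        return lab
    nbc = -(-ncol // block)
    rr = np.arange(nrow) // block
    cc = np.arange(ncol) // block
    raw = rr[:, None] * nbc + cc[None, :] + 1
    raw = np.where(domain_mask, raw, 0)
    uniq, inv = np.unique(raw, return_inverse=True)
    lab = inv.reshape(raw.shape).astype(np.int64)
    if uniq[0] != 0:  # no outside pixels at all
        lab += 1
    return lab


def multiresolution_segment(scene: Scene, domain_mask: np.ndarray,
                            params: SegmentationParams | None = None) -> SegmentMap:
    """Pairwise region merging of the domain into homogeneous objects."""
    params = params or SegmentationParams()
    domain_mask = domain_mask & ~scene.nodata_mask
    if not domain_mask.any():
        raise ConfigurationError("segmentation domain is empty")
    n_domain = int(domain_mask.sum())
    block = params.seed_block
    if block == "auto":
        block = _auto_block(n_domain)
    lab = _initial_labels(domain_mask, int(block))
    nreg = int(lab.max())

    weights = params.band_weights or {}
    band_names = [b for b in scene.band_names if weights.get(b, 1.0) > 0]
    wb = [float(weights.get(b, 1.0)) for b in band_names]
    bands = [scene.bands[b] for b in band_names]
    nb = len(bands)
    if nb == 0:
        raise ConfigurationError("at least one positive band weight is required")

    flat = lab.ravel()
    counts = np.bincount(flat, minlength=nreg + 1).astype(np.float64)
    sums = [np.bincount(flat, weights=a.ravel(), minlength=nreg + 1) for a in bands]
    sqs = [np.bincount(flat, weights=(a * a).ravel(), minlength=nreg + 1) for a in bands]

    # adjacency + shared boundary lengths from 4-neighbor pixel faces
    pairs = []
    same = np.zeros(nreg + 1, dtype=np.int64)
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        both = (a > 0) & (b > 0)
        eq = both & (a == b)
        same += np.bincount(a[eq], minlength=nreg + 1)
        diff = both & (a != b)
        if diff.any():
            lo = np.minimum(a[diff], b[diff])
            hi = np.maximum(a[diff], b[diff])
            pairs.append(lo * (nreg + 1) + hi)
    perim = 4.0 * counts - 2.0 * same
    if pairs:
        keys, shared_counts = np.unique(np.concatenate(pairs), return_counts=True)
    else:
        keys, shared_counts = np.array([], dtype=np.int64), np.array([], dtype=np.int64)

    # per-region python-level state for the merge loop
    n = counts.tolist()
    p = perim.tolist()
    S = [s.tolist() for s in sums]
    Q = [q.tolist() for q in sqs]
    rmin = [0] * (nreg + 1)
    rmax = [0] * (nreg + 1)
    cmin = [0] * (nreg + 1)
    cmax = [0] * (nreg + 1)
    rr_idx, cc_idx = np.nonzero(lab)
    ids = lab[rr_idx, cc_idx]
    order = np.argsort(ids, kind="stable")
    ids_s, rr_s, cc_s = ids[order], rr_idx[order], cc_idx[order]
    starts = np.searchsorted(ids_s, np.arange(1, nreg + 1))
    ends = np.searchsorted(ids_s, np.arange(1, nreg + 1), side="right")
    for i in range(1, nreg + 1):
        s, e = starts[i - 1], ends[i - 1]
        if s == e:
            continue
        rmin[i] = int(rr_s[s:e].min()); rmax[i] = int(rr_s[s:e].max())
        cmin[i] = int(cc_s[s:e].min()); cmax[i] = int(cc_s[s:e].max())

    adj = [dict() for _ in range(nreg + 1)]
    for key, cnt in zip(keys.tolist(), shared_counts.tolist()):
        lo, hi = divmod(key, nreg + 1)
        adj[lo][hi] = cnt
        adj[hi][lo] = cnt

    wc = 1.0 - params.shape
    ws = params.shape
    wcm = params.compactness
    scale2 = params.scale * params.scale
    sqrt = math.sqrt

    hcol = [0.0] * (nreg + 1)
    hshp = [0.0] * (nreg + 1)
    for i in range(1, nreg + 1):
        ni = n[i]
        if ni == 0:
            continue
        h = 0.0
        for b in range(nb):
            var = Q[b][i] / ni - (S[b][i] / ni) ** 2
            if var > 0:
                h += wb[b] * ni * sqrt(var)
        hcol[i] = h
        pb = 2.0 * (rmax[i] - rmin[i] + 1 + cmax[i] - cmin[i] + 1)
        hshp[i] = wcm * p[i] * sqrt(ni) + (1 - wcm) * ni * p[i] / pb

    ver = [0] * (nreg + 1)

    def merge_cost(i, j, shared):
        nm = n[i] + n[j]
        hc = 0.0
        for b in range(nb):
            s = S[b][i] + S[b][j]
            var = (Q[b][i] + Q[b][j]) / nm - (s / nm) ** 2
            if var > 0:
                hc += wb[b] * nm * sqrt(var)
        dh = wc * (hc - hcol[i] - hcol[j])
        if ws > 0:
            pm = p[i] + p[j] - 2.0 * shared
            r0 = rmin[i] if rmin[i] < rmin[j] else rmin[j]
            r1 = rmax[i] if rmax[i] > rmax[j] else rmax[j]
            c0 = cmin[i] if cmin[i] < cmin[j] else cmin[j]
            c1 = cmax[i] if cmax[i] > cmax[j] else cmax[j]
            pbm = 2.0 * (r1 - r0 + 1 + c1 - c0 + 1)
            hs = wcm * pm * sqrt(nm) + (1 - wcm) * nm * pm / pbm
            dh += ws * (hs - hshp[i] - hshp[j])
        return dh

    heap = []
    for i in range(1, nreg + 1):
        for j, shared in adj[i].items():
            if j > i:
                c = merge_cost(i, j, shared)
                if c < scale2:
                    heap.append((c, i, j, 0, 0))
    heapq.heapify(heap)
    parent = list(range(nreg + 1))

    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        cost, i, j, vi_, vj_ = pop(heap)
        if ver[i] != vi_ or ver[j] != vj_ or j not in adj[i]:
            continue
        # absorb j into i (i < j by construction)
        shared = adj[i].pop(j)
        nm = n[i] + n[j]
        hc = 0.0
        for b in range(nb):
            S[b][i] += S[b][j]
            Q[b][i] += Q[b][j]
            var = Q[b][i] / nm - (S[b][i] / nm) ** 2
            if var > 0:
                hc += wb[b] * nm * sqrt(var)
        n[i] = nm
        p[i] = p[i] + p[j] - 2.0 * shared
        if rmin[j] < rmin[i]: rmin[i] = rmin[j]
        if rmax[j] > rmax[i]: rmax[i] = rmax[j]
        if cmin[j] < cmin[i]: cmin[i] = cmin[j]
        if cmax[j] > cmax[i]: cmax[i] = cmax[j]
        hcol[i] = hc
        pb = 2.0 * (rmax[i] - rmin[i] + 1 + cmax[i] - cmin[i] + 1)
        hshp[i] = wcm * p[i] * sqrt(nm) + (1 - wcm) * nm * p[i] / pb
        parent[j] = i
        ver[i] += 1
        ver[j] = -1
        aj = adj[j]
        ai = adj[i]
        adj[j] = {}
        for k, cnt in aj.items():
            if k == i:
                continue
            ak = adj[k]
            del ak[j]
            ai[k] = ai.get(k, 0) + cnt
            ak[i] = ai[k]
        vi_now = ver[i]
        for k, cnt in ai.items():
            c = merge_cost(i, k, cnt) if i < k else merge_cost(k, i, cnt)
            if c < scale2:
                if i < k:
                    push(heap, (c, i, k, vi_now, ver[k]))
                else:
                    push(heap, (c, k, i, ver[k], vi_now))

    # resolve union-find roots and relabel compactly in scan order
    root_arr = np.zeros(nreg + 1, dtype=np.int64)
    for i in range(1, nreg + 1):
        root_arr[i] = _find(parent, i)
    final = root_arr[lab]
    uniq, inv = np.unique(final, return_inverse=True)
    final = inv.reshape(lab.shape)
    if uniq[0] != 0:
        final = final + 1
    final = final.astype(np.int32)
    seg = SegmentMap(labels=final, object_stats=compute_stats(final, scene))
    log.info("segmentation: %d seeds -> %d objects", nreg, seg.n_objects)
    return seg


def _find(parent, i):
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return i


def otsu_threshold(values, bins: int = 256, weights=None) -> float:
    """Histogram threshold maximizing between-class variance (Otsu).

    Values are binned into ``bins`` equal-width bins over their range; the
    returned threshold is the upper edge of the last bin of the lower class,
    mapped back to index units.
    """
    v = np.asarray(values, dtype=float).ravel()
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()
        ok = np.isfinite(v)
        v, weights = v[ok], weights[ok]
    else:
        v = v[np.isfinite(v)]
    if v.size < 2 or v.min() == v.max():
        raise DegenerateDistributionError(
            "Otsu threshold undefined: fewer than 2 distinct values")
    hist, edges = np.histogram(v, bins=bins, range=(v.min(), v.max()),
                               weights=weights)
    # between-class variance computed on integer bin indices (an affine map
    # of the bin centers, so the argmax is unchanged) keeps the arithmetic
    # exact for count histograms; ties — plateaus across empty gap bins —
    # break at the plateau midpoint
    w = hist.astype(float)
    total = w.sum()
    idx = np.arange(bins, dtype=float)
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * idx)
    w0 = cum_w[:-1]
    w1 = total - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = cum_m[:-1] / w0
        m1 = (cum_m[-1] - cum_m[:-1]) / w1
        between = w0 * w1 * (m0 - m1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    ties = np.flatnonzero(between == between.max())
    k = int(ties[len(ties) // 2])
    return float(edges[k + 1])


def classify_objects(segments: SegmentMap, index: vi.IndexRaster,
                     vine: VineMask, polarity: int | None = None,
                     transform: GeoTransform | None = None, crs=None,
                     level: str = "object", bins: int = 256,
                     nodata_mask: np.ndarray | None = None) -> ClassifiedMap:
    """Otsu-split the objects on their mean index value into weed vs soil."""
    if segments.n_objects < 2:
        raise ConfigurationError("need at least 2 objects to classify")
    if polarity is None:
        polarity = vi.get_definition(index.index_name).polarity

    nlab = int(segments.labels.max()) + 1
    flat = segments.labels.ravel()
    valid = ~index.mask.ravel()
    vals = np.where(valid, np.nan_to_num(index.values.ravel()), 0.0)
    sums = np.bincount(flat, weights=vals, minlength=nlab)
    cnts = np.bincount(flat, weights=valid.astype(float), minlength=nlab)
    with np.errstate(invalid="ignore"):
        means = sums / cnts
    labs = np.arange(1, nlab)
    have = cnts[1:] > 0
    if (~have).any():
        log.warning("%d objects have no valid index pixels; classed as bare soil",
                    int((~have).sum()))
    try:
        if level == "object":
            thr = otsu_threshold(means[1:][have], bins=bins,
                                 weights=np.bincount(flat, minlength=nlab)[1:][have])
        else:
            pix = index.values.ravel()[(flat > 0) & valid]
            thr = otsu_threshold(pix, bins=bins)
    except DegenerateDistributionError as exc:
        raise DegenerateDistributionError(
            f"{exc}; all objects carry an identical {index.index_name} value — "
            "check index polarity/scaling or provide a scene with both classes"
        ) from exc

    weed_obj = np.zeros(nlab, dtype=bool)
    side = polarity * (means[1:] - thr) > 0
    weed_obj[1:][have] = side[have]

    labels = np.full(segments.labels.shape, CLASS_CODES["nodata"], dtype=np.uint8)
    domain = segments.labels > 0
    labels[domain] = np.where(weed_obj[segments.labels[domain]],
                              CLASS_CODES["bermudagrass"], CLASS_CODES["bare_soil"])
    labels[vine.mask] = CLASS_CODES["vine"]
    if nodata_mask is not None:
        labels[nodata_mask] = CLASS_CODES["nodata"]

    pixel_area = transform.pixel_area if transform is not None else 1.0
    total = int((labels != CLASS_CODES["nodata"]).sum())
    area_summary = {}
    for cls, code in CLASS_CODES.items():
        if cls == "nodata":
            continue
        npx = int((labels == code).sum())
        area_summary[cls] = {
            "pixels": npx,
            "m2": npx * pixel_area,
            "pct": 100.0 * npx / total if total else 0.0,
        }
    return ClassifiedMap(labels=labels, area_summary=area_summary,
                         threshold_used=thr, index_name=index.index_name,
                         transform=transform, crs=crs)
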
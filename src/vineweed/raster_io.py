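"""Raster and vector I/O for the vineyard mapping pipeline.

Rasters are exchanged as GeoTIFFs written through :mod:`tifffile`: the
georeferencing is stored both in standard GeoTIFF tags (ModelPixelScale /
ModelTiepoint / ModelTransformation, GDAL nodata) and in a JSON payload in
the ImageDescription tag that additionally carries band names, camera type,
CRS identifier and the categorical code table. Vector inputs/outputs are
plain GeoJSON handled with :mod:`shapely`.

Class code table (fixed; written into raster metadata):
``{0: nodata/unknown, 1: vine, 2: bermudagrass, 3: bare_soil}``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape

from .errors import ConfigurationError, FormatError, LabelValidationError
from .geo import GeoTransform

log = logging.getLogger(__name__)

#: categorical code table shared by ClassifiedMap and LabelRaster rasters
CLASS_CODES = {"nodata": 0, "vine": 1, "bermudagrass": 2, "bare_soil": 3}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}
#: for label rasters code 0 means "unknown" (outside any sampling frame)
LABEL_UNKNOWN = 0

CAMERA_BANDS = {"RGB": ("R", "G", "B"), "RGNIR": ("R", "G", "NIR")}

_DESC_KEY = "vineweed"
_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_TRANSFORM = 34264
_TAG_GDAL_NODATA = 42113


@dataclass
class Scene:
    """A co-registered multiband scene: spectral bands + DSM.

    All 2-D arrays share one shape; ``nodata_mask`` is True where a pixel is
    invalid in any band, and nodata propagates into every downstream
    statistic and area total.
    """

    bands: dict
    dsm: np.ndarray
    transform: GeoTransform
    crs: str | None
    camera: str
    nodata_mask: np.ndarray = None

    def __post_init__(self):
        if self.camera not in CAMERA_BANDS:
            raise ConfigurationError(f"unknown camera {self.camera!r}")
        required = CAMERA_BANDS[self.camera]
        missing = [b for b in required if b not in self.bands]
        if missing:
            raise ConfigurationError(
                f"camera {self.camera} requires bands {required}; missing {missing}"
            )
        shapes = {name: b.shape for name, b in self.bands.items()}
        shapes["dsm"] = self.dsm.shape
        if len(set(shapes.values())) != 1:
            raise FormatError(f"band shapes differ: {shapes}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.dsm.shape, dtype=bool)
        if self.nodata_mask.shape != self.dsm.shape:
            raise FormatError("nodata mask shape mismatch")
        if not np.all(np.isfinite(self.dsm[~self.nodata_mask])):
            raise FormatError("DSM contains non-finite values outside nodata")

    @property
    def shape(self):
        return self.dsm.shape

    @property
    def band_names(self):
        return CAMERA_BANDS[self.camera]

    @property
    def pixel_area(self):
        return self.transform.pixel_area


@dataclass
class LabelRaster:
    """Ground-truth class codes on the Scene grid (0 = unknown)."""

    labels: np.ndarray
    transform: GeoTransform
    crs: str | None = None
    frame_ids: np.ndarray = None  # optional per-pixel sampling-frame index (-1 outside)

    def __post_init__(self):
        bad = set(np.unique(self.labels)) - set(CODE_NAMES)
        if bad:
            raise LabelValidationError(f"label codes outside vocabulary: {sorted(bad)}", bad)

    @property
    def shape(self):
        return self.labels.shape


def _meta_description(transform, crs, extra):
    payload = {"transform": transform.to_list(), "crs": crs}
    payload.update(extra)
    return json.dumps({_DESC_KEY: payload})


def _geotags(transform: GeoTransform, nodata=None):
    tags = []
    if transform.b == 0 and transform.d == 0:
        tags.append((_TAG_PIXELSCALE, "d", 3, (transform.a, -transform.e, 0.0)))
        tags.append((_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)))
    else:
        m = [transform.a, transform.b, 0.0, transform.c,
             transform.d, transform.e, 0.0, transform.f,
             0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0]
        tags.append((_TAG_TRANSFORM, "d", 16, tuple(m)))
    if nodata is not None:
        s = str(nodata)
        tags.append((_TAG_GDAL_NODATA, "s", len(s) + 1, s))
    return tags


def _parse_tiff_meta(tif):
    page = tif.pages[0]
    desc = page.tags.get("ImageDescription")
    meta = {}
    if desc is not None:
        try:
            payload = json.loads(desc.value)
            meta = payload.get(_DESC_KEY, {})
        except (json.JSONDecodeError, TypeError):
            meta = {}
    transform = None
    if "transform" in meta:
        transform = GeoTransform(*meta["transform"])
    else:
        scale = page.tags.get(_TAG_PIXELSCALE)
        tie = page.tags.get(_TAG_TIEPOINT)
        if scale is not None and tie is not None:
            sx, sy = scale.value[0], scale.value[1]
            x0, y0 = tie.value[3], tie.value[4]
            transform = GeoTransform(sx, 0.0, x0, 0.0, -sy, y0)
    nodata = meta.get("nodata")
    if nodata is None:
        tag = page.tags.get(_TAG_GDAL_NODATA)
        if tag is not None:
            nodata = float(tag.value)
    return meta, transform, nodata


def write_scene(scene: Scene, path, nodata=-10000.0):
    """Write a Scene as a multiband GeoTIFF (spectral bands then DSM)."""
    order = list(scene.band_names) + ["dsm"]
    stack = np.stack([scene.bands[b] if b != "dsm" else scene.dsm for b in order])
    stack = stack.astype(np.float32).copy()
    stack[:, scene.nodata_mask] = nodata
    desc = _meta_description(
        scene.transform, scene.crs,
        {"bands": order, "camera": scene.camera, "nodata": nodata},
    )
    tifffile.imwrite(
        path, stack, photometric="minisblack", description=desc,
        extratags=_geotags(scene.transform, nodata),
    )


def read_scene(raster_path, band_map=None, camera="RGB") -> Scene:
    """Read a georeferenced multiband raster into a Scene.

    Parameters
    ----------
    band_map : dict
        Band name -> 1-based band index; must cover the camera's spectral
        bands and ``"dsm"``. When omitted, the file's own metadata (written
        by :func:`write_scene`) supplies the layout.
    """
    path = Path(raster_path)
    if not path.exists():
        raise FormatError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta, transform, nodata = _parse_tiff_meta(tif)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[0] > arr.shape[2]:
        arr = np.moveaxis(arr, -1, 0)  # (H, W, n) -> (n, H, W)
    if band_map is None:
        names = meta.get("bands")
        if names is None:
            raise ConfigurationError("no band_map given and file carries no band metadata")
        band_map = {n: i + 1 for i, n in enumerate(names)}
    camera = meta.get("camera", camera)
    required = list(CAMERA_BANDS.get(camera, ())) + ["dsm"]
    missing = [b for b in required if b not in band_map]
    if missing:
        raise ConfigurationError(f"band_map missing required bands: {missing}")
    for name, idx in band_map.items():
        if not 1 <= idx <= arr.shape[0]:
            raise FormatError(f"band {name!r} index {idx} outside file with {arr.shape[0]} bands")
    if transform is None:
        warnings.warn("raster has no CRS/geotransform; assuming 1 m pixels at origin")
        transform = GeoTransform.north_up(0.0, 0.0, 1.0)
        crs = None
    else:
        crs = meta.get("crs")
    data = {n: arr[i - 1].astype(np.float64) for n, i in band_map.items()}
    dsm = data.pop("dsm")
    mask = np.zeros(dsm.shape, dtype=bool)
    if nodata is not None:
        for b in list(data.values()) + [dsm]:
            mask |= b == nodata
    for b in list(data.values()) + [dsm]:
        mask |= ~np.isfinite(b)
    dsm = dsm.copy()
    dsm[mask] = 0.0
    return Scene(bands=data, dsm=dsm, transform=transform, crs=crs,
                 camera=camera, nodata_mask=mask)


def write_label_raster(labels: LabelRaster, path):
    desc = _meta_description(labels.transform, labels.crs,
                             {"codes": CLASS_CODES, "kind": "labels"})
    tifffile.imwrite(path, labels.labels.astype(np.uint8), description=desc,
                     extratags=_geotags(labels.transform, 255))


def read_labels(vector_or_raster_path, scene: Scene) -> LabelRaster:
    """Read GT labels (GeoJSON polygons or categorical raster) onto the Scene grid.

    Polygon features must carry a ``class`` (or ``label``) property from the
    class vocabulary; pixels outside every polygon are ``unknown``. A CRS
    mismatch with the Scene raises instead of reprojecting.
    """
    path = Path(vector_or_raster_path)
    if path.suffix.lower() in {".json", ".geojson"}:
        with open(path) as fh:
            collection = json.load(fh)
        return rasterize_labels(collection, scene)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta, transform, _ = _parse_tiff_meta(tif)
    if arr.shape != scene.shape:
        raise FormatError(f"label raster shape {arr.shape} != scene shape {scene.shape}")
    if transform is not None and not transform.almost_equals(scene.transform):
        raise FormatError("label raster geotransform differs from scene")
    crs = meta.get("crs")
    if crs is not None and scene.crs is not None and crs != scene.crs:
        raise FormatError(f"CRS mismatch: labels {crs!r} vs scene {scene.crs!r}")
    return LabelRaster(arr.astype(np.uint8), scene.transform, scene.crs)


def rasterize_labels(collection: dict, scene: Scene) -> LabelRaster:
    """Burn a GeoJSON FeatureCollection of class polygons onto the Scene grid."""
    features = collection.get("features", [])
    crs = _geojson_crs(collection)
    if crs is not None and scene.crs is not None and crs != scene.crs:
        raise FormatError(f"CRS mismatch: labels {crs!r} vs scene {scene.crs!r}")
    labels = np.zeros(scene.shape, dtype=np.uint8)
    frame_ids = np.full(scene.shape, -1, dtype=np.int32)
    bad = []
    for feat in features:
        props = feat.get("properties") or {}
        cls = props.get("class", props.get("label"))
        if cls not in CLASS_CODES or cls == "nodata":
            bad.append(cls)
    if bad:
        raise LabelValidationError(
            f"features with class values outside vocabulary: {sorted(set(map(str, bad)))}", bad)
    nrow, ncol = scene.shape
    any_hit = False
    for fid, feat in enumerate(features):
        geom = shapely_shape(feat["geometry"])
        cls = feat["properties"].get("class", feat["properties"].get("label"))
        minx, miny, maxx, maxy = geom.bounds
        (r0, c0) = scene.transform.rowcol(minx, maxy)
        (r1, c1) = scene.transform.rowcol(maxx, miny)
        rlo, rhi = sorted((int(r0), int(r1)))
        clo, chi = sorted((int(c0), int(c1)))
        rlo, rhi = max(rlo, 0), min(rhi + 1, nrow)
        clo, chi = max(clo, 0), min(chi + 1, ncol)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
        xs, ys = scene.transform.xy(rr.ravel(), cc.ravel())
        inside = shapely.intersects_xy(geom, xs, ys).reshape(rr.shape)
        if inside.any():
            any_hit = True
            sub = labels[rlo:rhi, clo:chi]
            sub[inside] = CLASS_CODES[cls]
            frame_ids[rlo:rhi, clo:chi][inside] = fid
    if features and not any_hit:
        warnings.warn("no label polygon intersects the scene extent; labels all unknown")
    return LabelRaster(labels, scene.transform, scene.crs, frame_ids=frame_ids)


def _geojson_crs(collection):
    crs = collection.get("crs")
    if isinstance(crs, dict):
        return crs.get("properties", {}).get("name")
    return crs


def write_classified(classified, path):
    """Write a ClassifiedMap as a single-band categorical GeoTIFF."""
    desc = _meta_description(
        classified.transform, classified.crs,
        {"codes": CLASS_CODES, "kind": "classified",
         "index": classified.index_name, "threshold": classified.threshold_used},
    )
    tifffile.imwrite(path, classified.labels.astype(np.uint8), description=desc,
                     extratags=_geotags(classified.transform, CLASS_CODES["nodata"]))


def read_classified_labels(path):
    """Read back a categorical GeoTIFF written by :func:`write_classified`."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta, transform, _ = _parse_tiff_meta(tif)
    return arr.astype(np.uint8), transform, meta


def write_grid_geojson(grid, path):
    """Write a PrescriptionGrid as GeoJSON polygons with coverage/treat attributes."""
    features = []
    for cell in grid.cells:
        props = {"cell_id": cell.cell_id, "coverage_pct": round(cell.coverage_pct, 4)}
        for t, flag in cell.treat.items():
            props[f"treat_{str(t).replace('.', '_')}"] = bool(flag)
        features.append({
            "type": "Feature",
            "geometry": json.loads(shapely.to_geojson(cell.polygon)),
            "properties": props,
        })
    payload = {"type": "FeatureCollection", "features": features}
    if grid.crs:
        payload["crs"] = {"type": "name", "properties": {"name": grid.crs}}
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh)
    except OSError as exc:
        raise FormatError(f"cannot write grid to {path}: {exc}") from exc


def write_outputs(obj, path, fmt="auto"):
    """Dispatch writer for ClassifiedMap (GeoTIFF) / PrescriptionGrid (GeoJSON)."""
    from .prescription import PrescriptionGrid
    from .segmentation import ClassifiedMap

    if fmt == "auto":
        fmt = "geotiff" if isinstance(obj, ClassifiedMap) else "geojson"
    if fmt == "geotiff" and isinstance(obj, ClassifiedMap):
        write_classified(obj, path)
    elif fmt == "geojson" and isinstance(obj, PrescriptionGrid):
        write_grid_geojson(obj, path)
    else:
        raise ConfigurationError(f"unknown output format {fmt!r} for {type(obj).__name__}")
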
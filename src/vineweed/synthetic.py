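"""Synthetic vineyard scenes for testing and calibration.

The generator emulates the imaged study system: drip-irrigated vineyards
with east-west rows at 2.5 m inter-row / 1.3 m intra-row spacing, vines
trained on a vertical trellis (canopy ~1.5 m above soil), irregular
prostrate bermudagrass patches confined to the inter-rows, and bare-soil
background, optionally on sloping terrain. Spectra are drawn per class from
configurable per-band normal distributions on a reflectance-like 0-1 scale;
bermudagrass is green-dominant with high NIR, bare soil brown with a flat
spectrum, so that greenness (ExGR-family) and NIR-normalized (GNDVI-family)
indices are bimodal between weed and soil.

Weed patches are Gaussian-smoothed thresholded noise blobs: smoothing scale
is set by the patch-radius distribution and the threshold is the quantile of
the smoothed field over the inter-row area that yields the requested
coverage, which makes the realized coverage track the target closely.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .geo import GeoTransform
from .raster_io import CAMERA_BANDS, CLASS_CODES, LabelRaster, Scene
from .separability import ClassSampleSet

__all__ = ["SceneSpec", "DEFAULT_CLASS_SPECTRA", "generate_scene", "sample_spectra"]

#: per-class, per-band (mean, sd) reflectance; vegetative bermudagrass is
#: green-dominant with high NIR, dry bare soil is a brighter, flatter brown,
#: vine canopy resembles the weed but darker in the visible
DEFAULT_CLASS_SPECTRA = {
    "bare_soil": {"R": (0.32, 0.030), "G": (0.22, 0.020), "B": (0.16, 0.022), "NIR": (0.26, 0.025)},
    "bermudagrass": {"R": (0.12, 0.025), "G": (0.27, 0.020), "B": (0.08, 0.020), "NIR": (0.55, 0.035)},
    "vine": {"R": (0.10, 0.022), "G": (0.23, 0.020), "B": (0.07, 0.018), "NIR": (0.58, 0.035)},
}


@dataclass
class SceneSpec:
    """Parameters of a synthetic vineyard scene (distances in meters)."""

    field_size: tuple = (30.0, 30.0)  # (east-west, north-south) extent
    pixel_size: float = 0.01
    camera: str = "RGB"
    row_azimuth: float = 90.0  # 90 deg = rows running east-west
    inter_row: float = 2.5
    intra_row: float = 1.3
    vine_row_width: float = 0.6
    vine_height: float = 1.5
    vine_height_jitter: float = 0.15
    soil_elevation: float = 100.0
    slope: tuple = (0.0, 0.0)  # dz/dx, dz/dy (m per m)
    soil_roughness: float = 0.02
    weed_coverage_target: float = 0.15  # fraction of the inter-row area
    patch_radius_mean: float = 1.0
    patch_radius_sd: float = 0.3
    class_spectra: dict = field(default_factory=lambda: DEFAULT_CLASS_SPECTRA)
    spectra_contrast: float = 1.0  # <1 shrinks class separation ("hard mode")
    seed: int = 0
    origin: tuple = (500000.0, 4170000.0)
    crs: str = "EPSG:32630"

    def validate(self):
        if not (0.0 <= self.weed_coverage_target <= 1.0):
            raise ConfigurationError("weed_coverage_target must be in [0, 1]")
        if self.inter_row <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("inter_row and pixel_size must be positive")
        for cls, bands in self.class_spectra.items():
            for b, (_, sd) in bands.items():
                if sd < 0:
                    raise ConfigurationError(f"negative sd for {cls}/{b}")


def _smooth_noise(rng, shape, sigma_px):
    z = gaussian_filter(rng.standard_normal(shape), sigma=max(sigma_px, 0.5))
    sd = z.std()
    return z / sd if sd > 0 else z


def _row_frame(spec: SceneSpec, x, y):
    """Along-row (u) and across-row (v) coordinates for a row azimuth."""
    a = np.deg2rad(spec.row_azimuth)
    u = x * np.sin(a) + y * np.cos(a)
    v = -x * np.cos(a) + y * np.sin(a)
    return u, v


def _weed_mask(spec, rng, shape, inter_row_mask, px):
    """Irregular patches hitting the coverage target over the inter-row area."""
    target = spec.weed_coverage_target
    if target == 0:
        return np.zeros(shape, dtype=bool)
    n_inter = int(inter_row_mask.sum())
    if n_inter == 0:
        raise ConfigurationError("no inter-row area to place weed patches in")
    sig_main = spec.patch_radius_mean / px
    sig_fine = max(spec.patch_radius_mean - spec.patch_radius_sd, 4 * px) / px
    for _ in range(5):  # bounded retries; the quantile rule almost never misses
        f = _smooth_noise(rng, shape, sig_main)
        if spec.patch_radius_sd > 0:
            f = f + 0.5 * _smooth_noise(rng, shape, sig_fine)
        tau = np.quantile(f[inter_row_mask], 1.0 - target)
        weed = (f > tau) & inter_row_mask
        realized = weed.sum() / n_inter
        if target == 0 or abs(realized - target) <= 0.10 * target:
            return weed
    raise ConfigurationError(
        f"could not realize weed coverage {target:.3f} within 10% after retries")


def generate_scene(spec: SceneSpec):
    """Generate a (Scene, LabelRaster) pair; bit-deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    ncol = int(round(spec.field_size[0] / px))
    nrow = int(round(spec.field_size[1] / px))
    if nrow < 4 or ncol < 4:
        raise ConfigurationError("field too small for the requested pixel size")
    x0, y0 = spec.origin
    transform = GeoTransform.north_up(x0, y0 + nrow * px, px)
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    x, y = transform.xy(rows, cols)
    _, v = _row_frame(spec, x, y)

    # vine strips: canopy centerlines every inter_row across-row
    dist = np.abs((v + spec.inter_row / 2) % spec.inter_row - spec.inter_row / 2)
    vine = dist <= spec.vine_row_width / 2

    # terrain + canopy elevation
    sx, sy = spec.slope
    soil = (spec.soil_elevation + sx * (x - x.mean()) + sy * (y - y.mean())
            + spec.soil_roughness * _smooth_noise(rng, (nrow, ncol), 0.25 / px))
    canopy_jitter = spec.vine_height_jitter * _smooth_noise(
        rng, (nrow, ncol), max(spec.intra_row / 2, 2 * px) / px)
    height = np.clip(spec.vine_height + canopy_jitter, 0.2 * spec.vine_height, None)
    dsm = soil + np.where(vine, height, 0.0)

    weed = _weed_mask(spec, rng, (nrow, ncol), ~vine, px)

    labels = np.full((nrow, ncol), CLASS_CODES["bare_soil"], dtype=np.uint8)
    labels[weed] = CLASS_CODES["bermudagrass"]
    labels[vine] = CLASS_CODES["vine"]

    # class spectra, optionally contrast-shrunk toward the weed/soil midpoint
    spectra = spec.class_spectra
    if spec.spectra_contrast != 1.0:
        shrunk = {}
        for cls, bands in spectra.items():
            shrunk[cls] = {}
            for b, (m, s) in bands.items():
                mid = 0.5 * (spectra["bermudagrass"][b][0] + spectra["bare_soil"][b][0])
                shrunk[cls][b] = (mid + spec.spectra_contrast * (m - mid), s)
        spectra = shrunk

    bands = {}
    class_masks = [("vine", vine), ("bermudagrass", weed),
                   ("bare_soil", ~vine & ~weed)]
    for band in CAMERA_BANDS[spec.camera]:
        arr = np.empty((nrow, ncol), dtype=np.float64)
        for cls, mask in class_masks:
            m, s = spectra[cls][band]
            arr[mask] = m + s * rng.standard_normal(int(mask.sum()))
        bands[band] = np.clip(arr, 1e-3, None)

    scene = Scene(bands=bands, dsm=dsm, transform=transform, crs=spec.crs,
                  camera=spec.camera)
    return scene, LabelRaster(labels, transform, spec.crs)


def sample_spectra(scene: Scene, labels: LabelRaster, fraction: float,
                   seed: int) -> ClassSampleSet:
    """Simple random per-class sample (without replacement) of labeled pixels."""
    if not (0 < fraction <= 1):
        raise ConfigurationError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    samples = {}
    flat_ok = ~scene.nodata_mask.ravel()
    for cls in ("bermudagrass", "bare_soil"):
        code = CLASS_CODES[cls]
        idx = np.flatnonzero((labels.labels.ravel() == code) & flat_ok)
        if idx.size == 0:
            raise ConfigurationError(f"no labeled pixels for class {cls!r}")
        k = idx.size if fraction == 1 else max(1, int(round(fraction * idx.size)))
        chosen = np.sort(rng.choice(idx, size=k, replace=False))
        samples[cls] = {b: scene.bands[b].ravel()[chosen] for b in scene.band_names}
    return ClassSampleSet(samples=samples, camera=scene.camera,
                          provenance=f"synthetic sample fraction={fraction} seed={seed}")
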
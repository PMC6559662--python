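"""Vegetation-index registry: 14 RGB-range and 18 RGNIR-range indices.

Each index is an arithmetic combination of the R, G, B and NIR bands
computed on the native radiometric scale of the input (DN or reflectance)
with no rescaling; index values therefore depend on that scale, while the
downstream Otsu split of a single index is robust to monotone rescaling.

Every definition declares:

* ``cameras`` — which band sets it applies to;
* ``polarity`` — which side of a threshold is vegetation (+1: vegetation
  has the higher value, -1: the lower);
* ``homogeneity`` — behaviour under multiplying all bands by k > 0:
  ``"invariant"`` (value unchanged), ``"linear"`` (value scales by k) or
  ``"none"``.

Two printed formulas in the source literature are typographically
ambiguous.  MSR defaults to the established modified-simple-ratio
``(NIR/R - 1)/(sqrt(NIR/R) + 1)``; the no-square-root variant is available
via ``use_printed_msr``.  TVI1 is reconstructed as
``sign(NDVI + 0.5) * sqrt(|NDVI + 0.5|)``, consistent with the transformed
vegetation index family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigurationError
from .raster_io import Scene

__all__ = ["IndexDefinition", "IndexRaster", "REGISTRY", "list_indices",
           "compute_index", "evaluate", "get_definition"]


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    cameras: frozenset
    expression: Callable
    polarity: int  # +1: vegetation on the high side of a threshold
    homogeneity: str  # invariant | linear | none


@dataclass
class IndexRaster:
    values: np.ndarray  # float, NaN at masked pixels
    index_name: str
    mask: np.ndarray  # True where invalid (scene nodata or undefined value)

    @property
    def shape(self):
        return self.values.shape


def _veg(b):
    return b["G"] / (b["R"] ** 0.667 * b["B"] ** (1 - 0.667))


def _exg(b):
    return 2 * b["G"] - b["R"] - b["B"]


def _exr(b):
    return 1.4 * b["R"] - b["G"]


def _exgr(b):
    return _exg(b) - _exr(b)


def _cive(b):
    return 0.441 * b["R"] - 0.811 * b["G"] + 0.385 * b["B"] + 18.78745


def _ndvi(b):
    return (b["NIR"] - b["R"]) / (b["NIR"] + b["R"])


def _rvi(b):
    return b["R"] / b["NIR"]


def _msr_established(b):
    sr = b["NIR"] / b["R"]
    return (sr - 1) / (np.sqrt(sr) + 1)


def _msr_printed(b):
    sr = b["NIR"] / b["R"]
    return (sr - 1) / (sr + 1)


def _msavi(b):
    n = b["NIR"]
    return (2 * n + 1 - np.sqrt((2 * n + 1) ** 2 - 8 * (n - b["R"]))) / 2


def _tvi1(b):
    v = _ndvi(b) + 0.5
    return np.sign(v) * np.sqrt(np.abs(v))


_RGB = frozenset({"RGB"})
_NIRC = frozenset({"RGNIR"})
_BOTH = frozenset({"RGB", "RGNIR"})

use_printed_msr = False  # registry flag for the typographically printed MSR variant


def _msr(b):
    return _msr_printed(b) if use_printed_msr else _msr_established(b)


#: registry in stable (publication-table) order; ties in ranking break on it
REGISTRY: list[IndexDefinition] = [
    IndexDefinition("R/B", _RGB, lambda b: b["R"] / b["B"], -1, "invariant"),
    IndexDefinition("R/G", _BOTH, lambda b: b["R"] / b["G"], -1, "invariant"),
    IndexDefinition("NRGDI", _BOTH, lambda b: (b["G"] - b["R"]) / (b["G"] + b["R"]), +1, "invariant"),
    IndexDefinition("NPCI", _RGB, lambda b: (b["R"] - b["B"]) / (b["R"] + b["B"]), -1, "invariant"),
    IndexDefinition("VARI", _RGB, lambda b: (b["G"] - b["R"]) / (b["G"] + b["R"] - b["B"]), +1, "invariant"),
    IndexDefinition("WI", _RGB, lambda b: (b["G"] - b["B"]) / (b["R"] - b["G"]), -1, "invariant"),
    IndexDefinition("ExB", _RGB, lambda b: 1.4 * b["B"] - b["G"], -1, "linear"),
    IndexDefinition("ExG", _RGB, _exg, +1, "linear"),
    IndexDefinition("ExR", _BOTH, _exr, -1, "linear"),
    IndexDefinition("ExGR", _RGB, _exgr, +1, "linear"),
    IndexDefinition("CIVE", _RGB, _cive, -1, "none"),
    IndexDefinition("VEG", _RGB, _veg, +1, "invariant"),
    IndexDefinition("COMB1", _RGB,
                    lambda b: 0.25 * _exg(b) + 0.3 * _exgr(b) + 0.33 * _cive(b) + 0.12 * _veg(b),
                    +1, "none"),
    IndexDefinition("COMB2", _RGB,
                    lambda b: 0.36 * _exg(b) + 0.47 * _cive(b) + 0.17 * _veg(b),
                    +1, "none"),
    IndexDefinition("CI", _NIRC, lambda b: b["NIR"] / b["G"] - 1, +1, "invariant"),
    IndexDefinition("DVI", _NIRC, lambda b: b["NIR"] - b["R"], +1, "linear"),
    IndexDefinition("VIF", _NIRC, lambda b: b["NIR"] / (b["NIR"] + b["R"]), +1, "invariant"),
    IndexDefinition("GNDVI", _NIRC, lambda b: (b["NIR"] - b["G"]) / (b["NIR"] + b["G"]), +1, "invariant"),
    IndexDefinition("RVI", _NIRC, _rvi, -1, "invariant"),
    IndexDefinition("MRVI", _NIRC, lambda b: (_rvi(b) - 1) / (_rvi(b) + 1), -1, "invariant"),
    IndexDefinition("MSR", _NIRC, _msr, +1, "invariant"),
    IndexDefinition("MSAVI", _NIRC, _msavi, +1, "none"),
    IndexDefinition("NIR-G", _NIRC, lambda b: b["NIR"] - b["G"], +1, "linear"),
    IndexDefinition("NIR/G", _NIRC, lambda b: b["NIR"] / b["G"], +1, "invariant"),
    IndexDefinition("NLI", _NIRC,
                    lambda b: (b["NIR"] ** 2 - b["R"]) / (b["NIR"] ** 2 + b["R"]),
                    +1, "none"),
    IndexDefinition("NDVI", _NIRC, _ndvi, +1, "invariant"),
    IndexDefinition("OSAVI", _NIRC,
                    lambda b: (b["NIR"] - b["R"]) / (b["NIR"] + b["R"] + 0.16),
                    +1, "none"),
    IndexDefinition("TVI1", _NIRC, _tvi1, +1, "invariant"),
    IndexDefinition("TVI2", _NIRC,
                    lambda b: 0.5 * (120 * (b["NIR"] - b["G"]) - 200 * (b["R"] - b["G"])),
                    +1, "linear"),
]

_BY_NAME = {d.name: d for d in REGISTRY}
assert len(_BY_NAME) == len(REGISTRY), "duplicate index names"


def get_definition(name: str) -> IndexDefinition:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ConfigurationError(f"unknown vegetation index {name!r}") from None


def list_indices(camera: str) -> list[str]:
    """Names applicable to a camera, in stable registry order (14 RGB / 18 RGNIR)."""
    if camera not in {"RGB", "RGNIR"}:
        raise ConfigurationError(f"unknown camera {camera!r}")
    return [d.name for d in REGISTRY if camera in d.cameras]


def evaluate(name: str, bands: dict) -> np.ndarray:
    """Evaluate an index on a dict of band arrays/scalars (no masking)."""
    definition = get_definition(name)
    with np.errstate(divide="ignore", invalid="ignore"):
        return definition.expression(bands)


def compute_index(scene: Scene, name: str) -> IndexRaster:
    """Per-pixel index raster; zero-denominator and nodata pixels are masked."""
    definition = get_definition(name)
    if scene.camera not in definition.cameras:
        raise ConfigurationError(
            f"index {name!r} is not applicable to camera {scene.camera}"
        )
    values = np.asarray(evaluate(name, scene.bands), dtype=np.float64)
    mask = scene.nodata_mask | ~np.isfinite(values)
    values = values.copy()
    values[mask] = np.nan
    return IndexRaster(values=values, index_name=name, mask=mask)
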
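"""Spectral separability of bermudagrass vs bare soil.

For every vegetation index applicable to a camera, per-pixel index values of
the two classes are compared with (i) a one-way ANOVA followed by Tukey's
HSD test at alpha = 0.05 (for two groups the HSD decision coincides with the
F-test) and (ii) the M-statistic

    M = (mean_1 - mean_2) / (sigma_1 + sigma_2)

with sample standard deviations (n-1 denominator). Two class histograms are
conventionally called moderately separable when |M| > 1 and well separated
when |M| > 2. Indices are ranked by |M|; the rank-1 index is the one
implemented in the downstream object classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import indices as vi
from .errors import ConfigurationError, DegenerateDistributionError, LabelValidationError

log = logging.getLogger(__name__)

CLASS1, CLASS2 = "bermudagrass", "bare_soil"  # fixed class order for M

_CLASS_SYNONYMS = {
    "bermudagrass": CLASS1, "bermuda": CLASS1, "bg": CLASS1,
    "bare_soil": CLASS2, "bare soil": CLASS2, "baresoil": CLASS2,
    "soil": CLASS2, "bs": CLASS2,
}


@dataclass
class ClassSampleSet:
    """Labeled per-pixel band samples for the two ground classes."""

    samples: dict  # class -> {band -> 1-D float array}
    camera: str
    provenance: str = ""

    def __post_init__(self):
        for cls, bands in self.samples.items():
            lengths = {len(v) for v in bands.values()}
            if len(lengths) > 1:
                raise ConfigurationError(f"ragged band arrays for class {cls!r}")

    @property
    def classes(self):
        return list(self.samples)

    def n(self, cls):
        bands = self.samples[cls]
        return len(next(iter(bands.values())))

    def band_dict(self, cls):
        return {b: np.asarray(v, dtype=float) for b, v in self.samples[cls].items()}

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for cls, bands in self.samples.items():
            df = pd.DataFrame(bands)
            df.insert(0, "class", cls)
            parts.append(df)
        return pd.concat(parts, ignore_index=True)


@dataclass
class SeparabilityResult:
    index_name: str
    m_value: float
    anova_p: float
    tukey_significant: bool
    rank: int = 0

    @property
    def separability_label(self):
        a = abs(self.m_value)
        return "good" if a > 2 else ("moderate" if a > 1 else "poor")


def m_statistic(class1_values, class2_values) -> float:
    """Histogram separability M = (mean1 - mean2)/(sd1 + sd2), sample sds."""
    v1 = np.asarray(class1_values, dtype=float)
    v2 = np.asarray(class2_values, dtype=float)
    if v1.size < 2 or v2.size < 2:
        raise ConfigurationError("m_statistic needs at least 2 values per class")
    s1, s2 = v1.std(ddof=1), v2.std(ddof=1)
    if s1 + s2 == 0:
        raise DegenerateDistributionError(
            "both classes are constant; M is undefined")
    return float((v1.mean() - v2.mean()) / (s1 + s2))


def _index_values(samples: ClassSampleSet, index_name: str):
    """Finite per-pixel index values per class (undefined pixels dropped)."""
    out = {}
    for cls in (CLASS1, CLASS2):
        if cls not in samples.samples:
            raise ConfigurationError(f"sample set lacks class {cls!r}")
        vals = np.asarray(vi.evaluate(index_name, samples.band_dict(cls)), dtype=float)
        out[cls] = vals[np.isfinite(vals)]
    return out[CLASS1], out[CLASS2]


def anova_tukey(samples: ClassSampleSet, index_name: str):
    """One-way ANOVA p-value and Tukey-HSD significance (alpha 0.05) by class."""
    v1, v2 = _index_values(samples, index_name)
    if v1.size < 2 or v2.size < 2:
        raise ConfigurationError(f"too few finite values for index {index_name}")
    if v1.std() == 0 and v2.std() == 0 and v1.mean() == v2.mean():
        raise DegenerateDistributionError(
            f"index {index_name} constant across both classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_p = sps.f_oneway(v1, v2).pvalue
        hsd = pairwise_tukeyhsd(
            np.concatenate([v1, v2]),
            np.array([CLASS1] * v1.size + [CLASS2] * v2.size),
            alpha=0.05,
        )
    return float(f_p), bool(hsd.reject[0])


def rank_indices(samples: ClassSampleSet):
    """Rank all applicable indices by |M| (descending).

    Returns ``(results, selected_name)`` where results carry rank 1..n and
    selected is the rank-1 index. Ties break on registry order with a
    warning; indices degenerate on these samples are excluded.
    """
    names = vi.list_indices(samples.camera)
    raw = []
    for name in names:
        try:
            v1, v2 = _index_values(samples, name)
            m = m_statistic(v1, v2)
            p, sig = anova_tukey(samples, name)
        except DegenerateDistributionError:
            log.warning("index %s degenerate on samples; excluded from ranking", name)
            continue
        raw.append(SeparabilityResult(name, m, p, sig))
    if not raw:
        raise DegenerateDistributionError("every index is degenerate on these samples")
    order = sorted(range(len(raw)), key=lambda i: -abs(raw[i].m_value))
    results = []
    for rank, i in enumerate(order, start=1):
        raw[i].rank = rank
        results.append(raw[i])
    if len(results) > 1 and abs(results[0].m_value) == abs(results[1].m_value):
        log.warning("tie at rank 1 between %s and %s; registry order breaks it",
                    results[0].index_name, results[1].index_name)
    return results, results[0].index_name


def separability_report(results, top: int = 5) -> pd.DataFrame:
    """Top-ranked indices with M to 2 decimals and a qualitative band."""
    rows = [
        {
            "rank": r.rank,
            "index": r.index_name,
            "M": round(r.m_value, 2),
            "separability": r.separability_label,
            "anova_p": r.anova_p,
            "tukey_significant": r.tukey_significant,
        }
        for r in sorted(results, key=lambda r: r.rank)[:top]
    ]
    return pd.DataFrame(rows)


def read_sample_table(path, camera: str | None = None) -> ClassSampleSet:
    """Read a per-pixel sample table (CSV/XLSX, columns class,R,G,B or class,R,G,NIR)."""
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    cols = {c.strip().upper(): c for c in df.columns}
    if "CLASS" not in cols:
        raise ConfigurationError(f"{path}: no 'class' column (found {list(df.columns)})")
    has_nir = "NIR" in cols
    inferred = "RGNIR" if has_nir else "RGB"
    camera = camera or inferred
    band_cols = {"RGB": ("R", "G", "B"), "RGNIR": ("R", "G", "NIR")}[camera]
    missing = [b for b in band_cols if b not in cols]
    if missing:
        raise ConfigurationError(f"{path}: missing band columns {missing} for camera {camera}")
    classes = df[cols["CLASS"]].astype(str).str.strip().str.lower()
    mapped = classes.map(_CLASS_SYNONYMS)
    if mapped.isna().any():
        bad = sorted(classes[mapped.isna()].unique())
        raise LabelValidationError(f"{path}: unknown class values {bad}", bad)
    samples = {}
    for cls in (CLASS1, CLASS2):
        sub = df.loc[mapped.values == cls]
        if len(sub):
            samples[cls] = {b: sub[cols[b]].to_numpy(dtype=float) for b in band_cols}
    return ClassSampleSet(samples=samples, camera=camera, provenance=str(path))
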
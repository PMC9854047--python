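"""Vegetation-index baselines computed from resampled spectra.

Five classical ratio indices contrasting near-infrared with visible
reflectance serve as baselines for nutrient prediction.  ``R_800`` means
reflectance at the band center nearest 800 nm; ``R_{800-900}`` means the
mean reflectance over band centers in that range, truncated to the
available grid (the default grid stops at 850 nm, so ``R_{800-900}``
becomes the 800-850 nm mean — logged prominently when it happens).

As-printed vs canonical forms: the SAVI/OSAVI expressions reproduced here
apply the 1.5 / 1.16 factor to the first numerator term only, as the
source tables print them; ``canonical_savi=True`` switches to the
textbook forms that scale the whole NIR-red difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import pearson_r
from .preprocess import ResampledSpectra

logger = logging.getLogger(__name__)

__all__ = [
    "INDEX_NAMES",
    "VegIndexSpec",
    "band_at",
    "band_mean",
    "compute_index",
    "compute_all_indices",
    "index_cv_correlations",
]

INDEX_NAMES = ("SR", "NDVI", "GNDVI", "SAVI", "OSAVI")


@dataclass
class VegIndexSpec:
    """Name plus the wavelength arguments an index formula consumes."""

    name: str
    points: tuple = ()   # single-wavelength terms, nm
    ranges: tuple = ()   # (lo, hi) averaged terms, nm
    constants: tuple = ()


INDEX_SPECS = {
    "SR": VegIndexSpec("SR", ranges=((800, 900), (650, 700))),
    "NDVI": VegIndexSpec("NDVI", points=(800, 680)),
    "GNDVI": VegIndexSpec("GNDVI", ranges=((800, 900), (540, 560))),
    "SAVI": VegIndexSpec("SAVI", ranges=((800, 900), (650, 700)), constants=(1.5, 0.5)),
    "OSAVI": VegIndexSpec("OSAVI", points=(800, 670), constants=(1.16, 0.16)),
}


def band_at(spectra: ResampledSpectra, wavelength: float) -> np.ndarray:
    """Per-plot reflectance at the band center nearest ``wavelength``.

    Exact ties between two centers resolve to the lower one.
    """
    centers = spectra.band_centers
    dist = np.abs(centers - wavelength)
    j = int(np.flatnonzero(dist == dist.min())[0])  # lower center wins ties
    return spectra.X[:, j]


def band_mean(spectra: ResampledSpectra, lo: float, hi: float) -> np.ndarray:
    """Per-plot mean reflectance over band centers in [lo, hi].

    The range is truncated to the available grid; an empty intersection
    is an error.  A single point (lo == hi) maps to the nearest band.
    """
    if lo > hi:
        raise ValueError("band range requires lo <= hi")
    if lo == hi:
        return band_at(spectra, lo)
    centers = spectra.band_centers
    mask = (centers >= lo) & (centers <= hi)
    if not mask.any():
        raise ValueError(
            f"range [{lo}, {hi}] nm does not intersect the band grid "
            f"[{centers[0]}, {centers[-1]}] nm"
        )
    if hi > centers[-1] or lo < centers[0]:
        logger.warning(
            "range [%g, %g] nm truncated to available grid [%g, %g] nm",
            lo, hi, centers[0], centers[-1],
        )
    return spectra.X[:, mask].mean(axis=1)


def _safe_ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    if not ok.all():
        logger.warning(
            "%s: zero denominator for %d plot(s); values set to NaN",
            name, int((~ok).sum()),
        )
    out[ok] = num[ok] / den[ok]
    return out


def compute_index(
    name: str, spectra: ResampledSpectra, canonical_savi: bool = False
) -> np.ndarray:
    """Per-plot value of one vegetation index.

    SR    = R_{800-900} / R_{650-700}
    NDVI  = (R_800 - R_680) / (R_800 + R_680)
    GNDVI = (R_{800-900} - R_{540-560}) / (R_{800-900} + R_{540-560})
    SAVI  = (1.5 R_{800-900} - R_{650-700}) / (R_{800-900} + R_{650-700} + 0.5)
    OSAVI = (1.16 R_800 - R_670) / (R_800 + R_670 + 0.16)

    (as printed; ``canonical_savi`` scales the whole difference instead).
    """
    name = name.upper()
    if name == "SR":
        nir = band_mean(spectra, 800, 900)
        red = band_mean(spectra, 650, 700)
        return _safe_ratio(nir, red, name)
    if name == "NDVI":
        nir = band_at(spectra, 800)
        red = band_at(spectra, 680)
        return _safe_ratio(nir - red, nir + red, name)
    if name == "GNDVI":
        nir = band_mean(spectra, 800, 900)
        green = band_mean(spectra, 540, 560)
        return _safe_ratio(nir - green, nir + green, name)
    if name == "SAVI":
        nir = band_mean(spectra, 800, 900)
        red = band_mean(spectra, 650, 700)
        num = 1.5 * (nir - red) if canonical_savi else 1.5 * nir - red
        return _safe_ratio(num, nir + red + 0.5, name)
    if name == "OSAVI":
        nir = band_at(spectra, 800)
        red = band_at(spectra, 670)
        num = 1.16 * (nir - red) if canonical_savi else 1.16 * nir - red
        return _safe_ratio(num, nir + red + 0.16, name)
    raise ValueError(f"unknown vegetation index {name!r}; choose from {INDEX_NAMES}")


def compute_all_indices(
    spectra: ResampledSpectra, canonical_savi: bool = False
) -> pd.DataFrame:
    """All five indices as a plot-indexed DataFrame."""
    frame = pd.DataFrame({"plot_id": spectra.plot_ids})
    for name in INDEX_NAMES:
        frame[name] = compute_index(name, spectra, canonical_savi=canonical_savi)
    return frame


def index_cv_correlations(
    name: str,
    spectra: ResampledSpectra,
    y: np.ndarray,
    splits: list,
    canonical_savi: bool = False,
) -> dict:
    """Mean held-out Pearson correlation of one index with the log response.

    The same test subsets used for the model cross-validation score the
    raw index values directly (Pearson r is invariant to any linear
    calibration of the index, so no regression refit is needed).  Repeats
    where the correlation is undefined (constant index on the test set)
    are flagged and excluded from the mean.
    """
    values = compute_index(name, spectra, canonical_savi=canonical_savi)
    y = np.asarray(y, dtype=float)
    rs = []
    for rep, (_, test) in enumerate(splits):
        v = values[test]
        if np.isnan(v).any():
            logger.warning("%s repeat %d: NaN index values on test set", name, rep)
        r = pearson_r(v, y[test])
        if not np.isfinite(r):
            logger.warning(
                "%s repeat %d: correlation undefined; repeat excluded", name, rep
            )
        rs.append(r)
    rs = np.array(rs)
    valid = np.isfinite(rs)
    return {
        "index": name,
        "per_repeat": rs,
        "mean_r": float(rs[valid].mean()) if valid.any() else float("nan"),
    }
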
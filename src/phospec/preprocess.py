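"""Spectral preprocessing: windowing, B-spline resampling, dataset assembly.

Raw canopy reflectance arrives on a dense, noisy sensor grid (hundreds to
thousands of bands, with missing values concentrated at the spectrum
edges).  The pipeline restricts to an informative wavelength window
(450-850 nm by default), fits a least-squares cubic B-spline per plot, and
evaluates it on a coarse 4 nm grid — 101 bands for the default window —
which both denoises and collapses the near-duplicate neighboring bands
into a design matrix a regression can digest.

The response is the natural logarithm of grain phosphorus concentration,
so the regression dataset pairs ``y_i = ln(grain_p_i)`` with the
resampled reflectance row ``x_i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_lsq_spline

logger = logging.getLogger(__name__)

__all__ = [
    "RawSpectra",
    "ResampledSpectra",
    "RegressionDataset",
    "default_band_centers",
    "filter_window",
    "resample_bsplines",
    "assemble_dataset",
    "read_spectra",
    "read_phenotypes",
]

#: bounds applied after resampling; Spectralon-referenced reflectance can
#: mildly exceed 1 on bright canopies, hence the asymmetric cap.
REFLECTANCE_CLAMP = (0.0, 1.5)


@dataclass
class RawSpectra:
    """Long-format raw spectra: one row per (plot, wavelength).

    Wavelengths must be strictly increasing within each plot; reflectance
    may be missing (NaN) but must be finite where present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"plot_id", "wavelength_nm", "reflectance"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"raw spectra need columns {sorted(required)}")
        refl = self.data["reflectance"]
        if np.isinf(refl.to_numpy(dtype=float)).any():
            raise ValueError("reflectance contains infinite values")
        for pid, grp in self.data.groupby("plot_id", sort=False):
            wl = grp["wavelength_nm"].to_numpy(dtype=float)
            if np.any(np.diff(wl) <= 0):
                raise ValueError(
                    f"wavelengths not strictly increasing for plot {pid!r}"
                )

    @property
    def plot_ids(self) -> list:
        return list(dict.fromkeys(self.data["plot_id"]))

    def wavelength_range(self) -> tuple:
        wl = self.data["wavelength_nm"]
        return float(wl.min()), float(wl.max())


@dataclass
class ResampledSpectra:
    """Plot x band reflectance matrix on a regular wavelength grid."""

    plot_ids: list
    band_centers: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.plot_ids), self.band_centers.size):
            raise ValueError("X shape disagrees with plot_ids/band_centers")
        if np.isnan(self.X).any():
            raise ValueError("resampled spectra must not contain NaN")

    @property
    def n_bands(self) -> int:
        return self.band_centers.size

    def band_labels(self) -> list:
        return [f"b{int(round(c))}" for c in self.band_centers]

    def to_wide_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=[f"{c:g}" for c in self.band_centers])
        frame.insert(0, "plot_id", self.plot_ids)
        return frame

    def to_csv(self, path) -> None:
        self.to_wide_frame().to_csv(path, index=False)

    @classmethod
    def from_wide_frame(cls, frame: pd.DataFrame) -> "ResampledSpectra":
        plot_ids = frame.iloc[:, 0].tolist()
        centers = np.array([float(c) for c in frame.columns[1:]])
        return cls(plot_ids, centers, frame.iloc[:, 1:].to_numpy(dtype=float))


@dataclass
class RegressionDataset:
    """Aligned response/design pair for the Bayesian band-selection models.

    ``y`` is log grain phosphorus, ``X`` the resampled reflectance matrix;
    rows follow the field-layout plot order so that spatial structures
    indexed by plot apply directly.
    """

    y: np.ndarray
    X: np.ndarray
    plot_ids: list
    band_centers: np.ndarray
    pheno: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("y and X row counts disagree")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


def default_band_centers(lo: float = 450.0, hi: float = 850.0, step: float = 4.0) -> np.ndarray:
    """Arithmetic band-center grid: lo, lo+step, ..., hi (inclusive)."""
    n_bands = int(np.floor((hi - lo) / step)) + 1
    return lo + step * np.arange(n_bands)


def filter_window(raw: RawSpectra, lo: float, hi: float) -> RawSpectra:
    """Keep only wavelengths in the closed window [lo, hi].

    The plot set is unchanged; a plot whose spectrum would become empty is
    an error (it would silently vanish from the design otherwise).
    """
    if lo >= hi:
        raise ValueError("window requires lo < hi")
    before = raw.plot_ids
    mask = (raw.data["wavelength_nm"] >= lo) & (raw.data["wavelength_nm"] <= hi)
    filtered = raw.data.loc[mask].reset_index(drop=True)
    after = set(filtered["plot_id"])
    lost = [pid for pid in before if pid not in after]
    if lost:
        raise ValueError(
            f"window [{lo}, {hi}] leaves no wavelengths for plots: {lost}"
        )
    return RawSpectra(filtered)


def _interior_knots(x: np.ndarray, spacing: float, degree: int) -> np.ndarray:
    """Interior knots at data-site quantiles, roughly `spacing` nm apart.

    Quantile placement keeps every knot span populated with observations
    (the Schoenberg-Whitney condition) even when the raw grid is uneven.
    """
    span = x[-1] - x[0]
    m = int(np.floor(span / spacing)) - 1
    m = min(m, x.size - degree - 1)
    if m <= 0:
        return np.array([])
    probs = np.arange(1, m + 1) / (m + 1)
    return np.quantile(x, probs)


def resample_bsplines(
    raw: RawSpectra,
    band_centers: np.ndarray | None = None,
    degree: int = 3,
    knot_spacing: float = 8.0,
    clamp: tuple | None = REFLECTANCE_CLAMP,
) -> ResampledSpectra:
    """Per-plot least-squares B-spline fit, evaluated at the band centers.

    A cubic spline with interior knots every ``knot_spacing`` nm is fitted
    to the non-missing (wavelength, reflectance) points of each plot by
    least squares and evaluated at ``band_centers``.  Because the fit is a
    projection onto the spline space, any spectrum that is itself a
    polynomial of degree <= 3 is reproduced exactly.

    Raises if a plot has fewer than ``degree + 1`` usable points or if a
    requested center lies outside the plot's observed range
    (extrapolation is refused).
    """
    if band_centers is None:
        band_centers = default_band_centers()
    band_centers = np.asarray(band_centers, dtype=float)
    plot_ids = raw.plot_ids
    X = np.empty((len(plot_ids), band_centers.size))
    grouped = dict(list(raw.data.groupby("plot_id", sort=False)))
    for i, pid in enumerate(plot_ids):
        grp = grouped[pid]
        wl = grp["wavelength_nm"].to_numpy(dtype=float)
        refl = grp["reflectance"].to_numpy(dtype=float)
        keep = np.isfinite(refl)
        wl, refl = wl[keep], refl[keep]
        if wl.size < degree + 1:
            raise ValueError(
                f"plot {pid!r}: only {wl.size} non-missing points, "
                f"need at least {degree + 1} for a degree-{degree} spline"
            )
        if band_centers[0] < wl[0] or band_centers[-1] > wl[-1]:
            raise ValueError(
                f"plot {pid!r}: band centers [{band_centers[0]}, "
                f"{band_centers[-1]}] extend beyond observed range "
                f"[{wl[0]}, {wl[-1]}]; extrapolation is not supported"
            )
        interior = _interior_knots(wl, knot_spacing, degree)
        t = np.r_[[wl[0]] * (degree + 1), interior, [wl[-1]] * (degree + 1)]
        spline = make_lsq_spline(wl, refl, t, k=degree)
        X[i] = spline(band_centers)
    if clamp is not None:
        out_of_range = (X < clamp[0]) | (X > clamp[1])
        if out_of_range.any():
            logger.warning(
                "%d resampled reflectance values outside [%g, %g]; clamped",
                int(out_of_range.sum()), clamp[0], clamp[1],
            )
            X = np.clip(X, clamp[0], clamp[1])
    return ResampledSpectra(plot_ids, band_centers, X)


def assemble_dataset(
    spectra: ResampledSpectra,
    pheno: pd.DataFrame,
    plot_order: list | None = None,
) -> RegressionDataset:
    """Join resampled spectra with phenotypes into an aligned (y, X) pair.

    Plot ids must match one-to-one.  ``plot_order`` (typically the field
    layout order) fixes the row order; by default the phenotype order is
    used.
    """
    spec_ids = set(spectra.plot_ids)
    pheno_ids = set(pheno["plot_id"])
    missing_spec = sorted(pheno_ids - spec_ids)
    missing_pheno = sorted(spec_ids - pheno_ids)
    if missing_spec or missing_pheno:
        raise ValueError(
            "plot ids do not match one-to-one; "
            f"missing spectra for {missing_spec}, "
            f"missing phenotypes for {missing_pheno}"
        )
    if not spec_ids:
        raise ValueError("no plots in common between spectra and phenotypes")
    order = list(plot_order) if plot_order is not None else pheno["plot_id"].tolist()
    if set(order) != spec_ids:
        raise ValueError("plot_order does not cover exactly the shared plot ids")
    spec_pos = {pid: i for i, pid in enumerate(spectra.plot_ids)}
    pheno_indexed = pheno.set_index("plot_id")
    X = spectra.X[[spec_pos[pid] for pid in order]]
    pheno_sorted = pheno_indexed.loc[order].reset_index()
    if "y" in pheno_sorted.columns:
        y = pheno_sorted["y"].to_numpy(dtype=float)
    else:
        y = np.log(pheno_sorted["grain_p"].to_numpy(dtype=float))
    return RegressionDataset(
        y=y,
        X=X,
        plot_ids=order,
        band_centers=spectra.band_centers,
        pheno=pheno_sorted,
    )


def read_spectra(path) -> RawSpectra:
    """Read spectra from CSV, auto-detecting long vs wide layout.

    Long: columns (plot_id, wavelength_nm, reflectance).  Wide: first
    column plot_id, remaining columns labelled by wavelength in nm.
    """
    frame = pd.read_csv(path)
    cols = {c.lower() for c in frame.columns}
    if {"plot_id", "wavelength_nm", "reflectance"}.issubset(cols):
        frame.columns = [c.lower() for c in frame.columns]
        return RawSpectra(frame[["plot_id", "wavelength_nm", "reflectance"]])
    # wide: melt into long, sorting each plot by wavelength
    id_col = frame.columns[0]
    try:
        wavelengths = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise ValueError(
            "wide spectra CSV must have numeric wavelength column labels"
        ) from exc
    order = np.argsort(wavelengths)
    long = pd.DataFrame(
        {
            "plot_id": np.repeat(frame[id_col].to_numpy(), wavelengths.size),
            "wavelength_nm": np.tile(wavelengths[order], len(frame)),
            "reflectance": frame.iloc[:, 1:].to_numpy(dtype=float)[:, order].ravel(),
        }
    )
    return RawSpectra(long)


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype table and derive the log response column ``y``."""
    frame = pd.read_csv(path)
    required = {"plot_id", "year", "genotype", "p_level", "rep", "grain_p"}
    if not required.issubset(frame.columns):
        raise ValueError(f"phenotype CSV needs columns {sorted(required)}")
    grain_p = frame["grain_p"].to_numpy(dtype=float)
    if np.any(~np.isfinite(grain_p)) or np.any(grain_p <= 0):
        raise ValueError("grain_p must be finite and > 0")
    frame = frame.copy()
    frame["y"] = np.log(grain_p)
    return frame
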
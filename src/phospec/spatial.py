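"""Field geometry for plot-level spatial models.

A wheat trial is laid out on a rectangular grid of plots.  Two notions of
spatial structure are used downstream:

* a *neighborhood* (areal) structure — the binary adjacency matrix ``M``
  with row-sum diagonal ``D_M`` that defines the conditionally
  autoregressive (CAR) joint distribution
  ``y ~ N(X beta, tau2 * (D_M - phi * M)^{-1})``; and
* a *geostatistical* structure — Euclidean distances between plot
  centroids feeding the isotropic exponential correlogram
  ``H(phi)_ij = exp(-phi * ||s_i - s_j||)``.

The admissible range of the CAR autocorrelation parameter ``phi`` is tied
to the ordered eigenvalues ``lambda_(1) < ... < lambda_(n)`` of the scaled
adjacency ``D_M^{-1/2} M D_M^{-1/2}``: the precision ``D_M - phi M`` is
positive definite exactly when ``1/lambda_(1) < phi < 1/lambda_(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

__all__ = [
    "FieldStructure",
    "build_layout",
    "layout_from_frame",
    "euclidean_distances",
    "exp_correlation",
    "car_precision",
]


@dataclass
class FieldStructure:
    """Plot coordinates plus the CAR neighborhood structure.

    Attributes
    ----------
    plot_ids : list of str
        Plot identifiers, in the canonical row order of the design.
    coords : ndarray, shape (n, 2)
        Plot centroid coordinates in metres.
    M : ndarray, shape (n, n)
        Binary symmetric adjacency matrix with zero diagonal.
    """

    plot_ids: list
    coords: np.ndarray
    M: np.ndarray
    d_m: np.ndarray = field(init=False)
    eigenvalues: np.ndarray = field(init=False)
    phi_support: tuple = field(init=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        n = M.shape[0]
        if M.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        if len(self.plot_ids) != n or self.coords.shape != (n, 2):
            raise ValueError("plot_ids, coords and M sizes disagree")
        if not np.array_equal(M, M.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(M) != 0):
            raise ValueError("adjacency matrix must have zero diagonal")
        if not np.isin(M, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        rowsums = M.sum(axis=1)
        isolated = np.flatnonzero(rowsums == 0)
        if isolated.size:
            names = [self.plot_ids[i] for i in isolated]
            raise ValueError(f"plots with no neighbor: {names}")
        self.M = M
        self.d_m = rowsums
        # eigenvalues of D^{-1/2} M D^{-1/2}; symmetric, so eigh
        d_isqrt = 1.0 / np.sqrt(rowsums)
        scaled = M * d_isqrt[:, None] * d_isqrt[None, :]
        lam = eigh(scaled, eigvals_only=True)
        self.eigenvalues = np.sort(lam)
        lam_min, lam_max = self.eigenvalues[0], self.eigenvalues[-1]
        if not (lam_min < 0 < lam_max):
            raise ValueError("scaled adjacency must have eigenvalues of both signs")
        self.phi_support = (1.0 / lam_min, 1.0 / lam_max)

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def D_M(self) -> np.ndarray:
        """Row-sum diagonal matrix of the adjacency."""
        return np.diag(self.d_m)

    def distances(self) -> np.ndarray:
        return euclidean_distances(self.coords)

    def subset(self, idx: np.ndarray) -> "FieldStructure":
        """Restrict to a subset of plots, rebuilding adjacency from scratch.

        Note: training-only CAR likelihoods do NOT use this — they take the
        principal submatrix of the full-field precision ``D_M - phi M``
        (full-field row sums), which the model classes handle via row
        indices into the complete layout.
        """
        idx = np.asarray(idx)
        return FieldStructure(
            plot_ids=[self.plot_ids[i] for i in idx],
            coords=self.coords[idx],
            M=self.M[np.ix_(idx, idx)],
        )

    def to_edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.M))
        return pd.DataFrame(
            {
                "plot_a": [self.plot_ids[a] for a in i],
                "plot_b": [self.plot_ids[b] for b in j],
            }
        )


def build_layout(
    n_rows: int,
    n_cols: int,
    plot_dx: float = 3.2,
    plot_dy: float = 5.0,
    n_plots: int | None = None,
    plot_ids: list | None = None,
    adjacency: str = "rook",
) -> FieldStructure:
    """Build a rectangular grid of plot centroids with grid adjacency.

    Plots are placed row-major: plot ``k`` sits at column ``k % n_cols``,
    row ``k // n_cols``.  The default footprint (3.2 m x 5.0 m) matches a
    four-bed, 0.8 m bed plot of 5 m length.

    Parameters
    ----------
    adjacency : {"rook", "queen"}
        Rook neighbors share a grid edge; queen additionally shares corners.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    if plot_dx <= 0 or plot_dy <= 0:
        raise ValueError("plot dimensions must be positive")
    n = n_plots if n_plots is not None else n_rows * n_cols
    if n > n_rows * n_cols:
        raise ValueError(f"{n} plots do not fit a {n_rows}x{n_cols} grid")
    if adjacency not in ("rook", "queen"):
        raise ValueError("adjacency must be 'rook' or 'queen'")
    rows = np.arange(n) // n_cols
    cols = np.arange(n) % n_cols
    coords = np.column_stack([cols * plot_dx, rows * plot_dy]).astype(float)
    M = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            dr = abs(int(rows[a]) - int(rows[b]))
            dc = abs(int(cols[a]) - int(cols[b]))
            if adjacency == "rook":
                neighbor = dr + dc == 1
            else:
                neighbor = max(dr, dc) == 1
            if neighbor:
                M[a, b] = M[b, a] = 1.0
    if plot_ids is None:
        plot_ids = [f"plot_{k + 1:03d}" for k in range(n)]
    return FieldStructure(plot_ids=list(plot_ids), coords=coords, M=M)


def layout_from_frame(
    frame: pd.DataFrame,
    plot_dx: float = 3.2,
    plot_dy: float = 5.0,
    adjacency: str = "rook",
) -> FieldStructure:
    """Build a FieldStructure from a (plot_id, row, col) table."""
    required = {"plot_id", "row", "col"}
    if not required.issubset(frame.columns):
        raise ValueError(f"layout table needs columns {sorted(required)}")
    frame = frame.reset_index(drop=True)
    rows = frame["row"].to_numpy(dtype=int)
    cols = frame["col"].to_numpy(dtype=int)
    n = len(frame)
    coords = np.column_stack([cols * plot_dx, rows * plot_dy]).astype(float)
    M = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            dr = abs(rows[a] - rows[b])
            dc = abs(cols[a] - cols[b])
            if adjacency == "rook":
                neighbor = dr + dc == 1
            else:
                neighbor = max(dr, dc) == 1 and (dr + dc) >= 1
            if neighbor:
                M[a, b] = M[b, a] = 1.0
    return FieldStructure(
        plot_ids=frame["plot_id"].tolist(), coords=coords, M=M
    )


def euclidean_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix between plot centroids (metres)."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def exp_correlation(D: np.ndarray, phi: float) -> np.ndarray:
    """Isotropic exponential correlogram ``H_ij = exp(-phi * D_ij)``.

    ``phi`` has units 1/metre; larger values mean faster decay of spatial
    correlation with distance.
    """
    if phi <= 0:
        raise ValueError("exponential decay rate phi must be > 0")
    D = np.asarray(D, dtype=float)
    return np.exp(-phi * D)


def car_precision(fs: FieldStructure, phi: float, tau2: float) -> np.ndarray:
    """CAR precision matrix ``(D_M - phi * M) / tau2``.

    Positive definite exactly for ``phi`` strictly inside
    ``fs.phi_support``; values at or outside the support are rejected.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be > 0")
    lo, hi = fs.phi_support
    if not (lo < phi < hi):
        raise ValueError(
            f"phi={phi} outside the open CAR support ({lo:.4f}, {hi:.4f})"
        )
    return (np.diag(fs.d_m) - phi * fs.M) / tau2
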
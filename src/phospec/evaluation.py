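"""Chain summaries, DIC, cross-validation and index comparison.

Band selection is read off the chains two ways: by thresholding the
posterior inclusion probabilities (PIP >= 0.6 by convention) and by the
most probable submodel — the gamma configuration visited most often
("avgmod").  Model fit is compared by the deviance information criterion
DIC = Dbar + p_D, p_D = Dbar - D(theta_bar).  Predictive power is scored
by repeated random holdout (25 of 126 plots by default) with
model-appropriate spatial prediction for the held-out plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .priors import MCMCConfig
from .spatial import FieldStructure, euclidean_distances, exp_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionSummary",
    "FitSummary",
    "CVReport",
    "selection_summary",
    "compute_dic",
    "cv_split",
    "predict_heldout",
    "pearson_r",
    "run_cv",
    "compare_to_indices",
]


@dataclass
class SelectionSummary:
    """Posterior band-selection summary from the gamma chains."""

    pip: np.ndarray
    band_names: list
    threshold: float
    selected_indices: np.ndarray
    avgmod: np.ndarray
    avgmod_freq: float

    @property
    def selected_threshold(self) -> list:
        return [self.band_names[j] for j in self.selected_indices]

    @property
    def avgmod_indices(self) -> np.ndarray:
        return np.flatnonzero(self.avgmod)


@dataclass
class FitSummary:
    """DIC decomposition: dic = dbar + p_d, p_d = dbar - D(theta_bar)."""

    dic: float
    dbar: float
    p_d: float
    point_estimates: dict = field(default_factory=dict)


@dataclass
class CVRepeat:
    test_ids: np.ndarray
    predictions: np.ndarray
    observed: np.ndarray
    r: float


@dataclass
class CVReport:
    repeats: list

    @property
    def correlations(self) -> np.ndarray:
        return np.array([rep.r for rep in self.repeats])

    @property
    def mean_r(self) -> float:
        rs = self.correlations
        valid = np.isfinite(rs)
        if not valid.any():
            return float("nan")
        return float(rs[valid].mean())


def selection_summary(
    gamma_draws: np.ndarray, band_names: list | None = None, threshold: float = 0.6
) -> SelectionSummary:
    """Summarize gamma chains into PIPs and the most probable submodel.

    Ties in submodel frequency are broken toward the smaller model
    (fewer included bands), then lexicographically.
    """
    gamma_draws = np.asarray(gamma_draws)
    if gamma_draws.ndim != 2 or gamma_draws.shape[0] == 0:
        raise ValueError("gamma draws must be a nonempty (draws, p) array")
    p = gamma_draws.shape[1]
    if band_names is None:
        band_names = [f"x{j + 1}" for j in range(p)]
    pip = gamma_draws.mean(axis=0)
    models, counts = np.unique(gamma_draws, axis=0, return_counts=True)
    best = np.flatnonzero(counts == counts.max())
    # smaller model first, then lexicographic (np.unique rows are sorted)
    winner = min(best, key=lambda i: (models[i].sum(), tuple(models[i])))
    return SelectionSummary(
        pip=pip,
        band_names=list(band_names),
        threshold=threshold,
        selected_indices=np.flatnonzero(pip >= threshold),
        avgmod=models[winner].astype(np.int8),
        avgmod_freq=float(counts[winner] / gamma_draws.shape[0]),
    )


def compute_dic(
    deviance_draws: np.ndarray,
    deviance_at_posterior_mean: float,
    point_estimates: dict | None = None,
) -> FitSummary:
    """DIC from per-draw deviances and the deviance at the posterior mean."""
    deviance_draws = np.asarray(deviance_draws, dtype=float)
    if deviance_draws.size < 2:
        raise ValueError("DIC needs at least two kept draws")
    if not np.all(np.isfinite(deviance_draws)) or not np.isfinite(
        deviance_at_posterior_mean
    ):
        raise ValueError("non-finite deviance encountered")
    dbar = float(deviance_draws.mean())
    p_d = dbar - float(deviance_at_posterior_mean)
    return FitSummary(
        dic=dbar + p_d,
        dbar=dbar,
        p_d=p_d,
        point_estimates=point_estimates or {},
    )


def cv_split(n: int, n_test: int, repeats: int, seed: int) -> list:
    """Repeated random holdout splits: (train_idx, test_idx) per repeat.

    Each repeat draws a fresh size-``n_test`` test set uniformly without
    replacement; the complement is the training set.
    """
    if not 0 < n_test < n:
        raise ValueError("need 0 < n_test < n")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(repeats):
        test = np.sort(rng.choice(n, size=n_test, replace=False))
        train = np.setdiff1d(np.arange(n), test)
        splits.append((train, test))
    return splits


def _check_rows(fs: FieldStructure, rows: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=int)
    if rows.size and (rows.min() < 0 or rows.max() >= fs.n):
        raise ValueError("test plot indices fall outside the field layout")
    return rows


def predict_heldout(results, X_test: np.ndarray, test_rows: np.ndarray | None = None) -> np.ndarray:
    """Plug-in posterior-mean predictions for held-out plots.

    independent : X_test beta_hat
    geostat     : X_test beta_hat + H_21 H_11^{-1} w_hat  (simple kriging of
                  the latent field at the posterior-mean decay phi_hat)
    car         : X_test beta_hat + the conditional mean of the held-out
                  block of the joint CAR normal given the training
                  residuals, computed from the partitioned precision
                  Q = D_M - phi_hat M (tau2 cancels):
                  -Q_22^{-1} Q_21 (y_train - X_train beta_hat)
    """
    model = results.model
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    base = results.intercept_mean + X_test @ results.beta_mean
    if model.kind == "independent":
        return base
    if test_rows is None:
        raise ValueError("spatial prediction requires test plot indices")
    fs = model.field
    test_rows = _check_rows(fs, test_rows)
    train_rows = model.rows
    means = results.posterior_means()
    phi_hat = means["phi"]
    if model.kind == "geostat":
        if phi_hat <= 0:
            return base
        w_hat = means["w"]
        d_tr = euclidean_distances(fs.coords[train_rows])
        H11 = exp_correlation(d_tr, phi_hat) + 1e-10 * np.eye(train_rows.size)
        diff = fs.coords[test_rows][:, None, :] - fs.coords[train_rows][None, :, :]
        d_cross = np.sqrt((diff**2).sum(axis=-1))
        H21 = exp_correlation(d_cross, phi_hat)
        return base + H21 @ cho_solve(cho_factor(H11, lower=True), w_hat)
    # car
    Q = np.diag(fs.d_m) - phi_hat * fs.M
    r_train = model.y - (results.intercept_mean + model.X @ results.beta_mean)
    Q22 = Q[np.ix_(test_rows, test_rows)]
    Q21 = Q[np.ix_(test_rows, train_rows)]
    adjust = -cho_solve(cho_factor(Q22, lower=True), Q21 @ r_train)
    return base + adjust


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either input is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def run_cv(
    kind: str,
    dataset,
    fs: FieldStructure | None,
    splits: list,
    config: MCMCConfig,
    bands: np.ndarray | None = None,
    **model_kwargs,
) -> CVReport:
    """Repeated-holdout cross-validation for one model kind.

    For the spatial kinds the training fit sees only the training plots
    (training-restricted CAR precision / training-coordinate correlogram)
    and held-out plots are re-introduced only at prediction time through
    the full-field partitioned covariance.
    """
    from .models import make_model

    X = dataset.X if bands is None else dataset.X[:, np.asarray(bands, dtype=int)]
    y = dataset.y
    repeats = []
    for rep, (train, test) in enumerate(splits):
        cfg = MCMCConfig(
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=config.seed + 7919 * (rep + 1),
            phi_proposal_sd=config.phi_proposal_sd,
            adapt_phi=config.adapt_phi,
        )
        kwargs = dict(model_kwargs)
        if kind in ("geostat", "car"):
            kwargs.update(field=fs, rows=train)
        model = make_model(kind, y[train], X[train], **kwargs)
        res = model.fit(config=cfg)
        preds = res.predict(X[test], test_rows=test if kind != "independent" else None)
        r = pearson_r(y[test], preds)
        if not np.isfinite(r):
            logger.warning("repeat %d: correlation undefined (constant input)", rep)
        repeats.append(
            CVRepeat(test_ids=test, predictions=preds, observed=y[test], r=r)
        )
    return CVReport(repeats=repeats)


def compare_to_indices(car_mean_r: float, index_rs) -> float:
    """Percentage-point gap between the CAR mean CV correlation and the
    average vegetation-index correlation: 100 (r_car - mean(r_indices))."""
    index_rs = np.asarray(index_rs, dtype=float)
    if np.any(np.abs(index_rs) > 1) or abs(car_mean_r) > 1:
        raise ValueError("correlations must lie in [-1, 1]")
    return float(100.0 * (car_mean_r - index_rs.mean()))
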
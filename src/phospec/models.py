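"""Bayesian spike-and-slab regression models for plot-level spectra.

Three models for the log grain-phosphorus response ``y`` on the resampled
reflectance design ``X``, differing only in how residual spatial
structure is handled:

* ``IndependentModel`` — y_i = x_i' beta + eps_i, eps ~ N(0, sigma2),
  observations independent;
* ``GeostatModel``     — y_i = x_i' beta + w_i + eps_i with a latent
  Gaussian field w ~ N(0, sigma2 H(phi)), H the isotropic exponential
  correlogram on plot-centroid distances, and nugget eps ~ N(0, tau2);
* ``CARModel``         — jointly y ~ N(X beta, tau2 (D_M - phi M)^{-1}),
  the conditionally autoregressive model on the plot adjacency graph.

All three share the spike-and-slab coefficient prior that performs band
selection, inverse-gamma priors on variances, and (for the spatial
models) a uniform prior on phi.  Fitting is by a Gibbs sampler with a
Metropolis step for phi; ``fit`` returns an :class:`MCMCResults`.

Usage::

    model = CARModel.from_dataset(dataset, field)
    res = model.fit(n_iter=10_000, burn_in=5_000, thin=5, seed=1)
    res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .priors import MCMCConfig, PhiPrior, SpikeSlabPrior, VariancePrior
from . import sampling
from .sampling import (
    car_logdet,
    car_quadform,
    gaussian_loglik,
    loglik_car,
    sweep_coefficients,
    update_phi_mh,
    update_variance,
    update_w,
)
from .spatial import FieldStructure, euclidean_distances, exp_correlation

__all__ = [
    "MODEL_KINDS",
    "PosteriorSamples",
    "IndependentModel",
    "GeostatModel",
    "CARModel",
    "make_model",
    "fit_model",
    "loglik",
]

MODEL_KINDS = ("independent", "geostat", "car")

#: effectively-flat normal prior variance for the intercept
_INTERCEPT_NU = 1.0e6
#: diagonal jitter stabilizing the correlogram factorization inside chains
_H_JITTER = 1.0e-8


@dataclass
class PosteriorSamples:
    """Thinned posterior draws, on the original predictor scale.

    ``beta`` has one column per band; in every draw ``beta[d, j]`` is
    exactly zero whenever ``gamma[d, j] == 0``.  ``sigma2``/``tau2``/
    ``phi``/``w`` are present only for model kinds that carry them.
    ``deviance`` is -2 log-likelihood per kept draw.
    """

    intercept: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    deviance: np.ndarray
    sigma2: np.ndarray | None = None
    tau2: np.ndarray | None = None
    phi: np.ndarray | None = None
    w: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.intercept.size


class BaseSpectralModel:
    """Shared constructor, standardization and MCMC loop for all kinds."""

    kind: str = ""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        field: FieldStructure | None = None,
        rows: np.ndarray | None = None,
        band_names: list | None = None,
        spike_slab: SpikeSlabPrior | None = None,
        variance_prior: VariancePrior | None = None,
        phi_prior: PhiPrior | None = None,
        select: bool = True,
        standardize: bool = True,
    ) -> None:
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise ValueError("y and X row counts disagree")
        self.n, self.p = self.X.shape
        self.field = field
        if self.kind in ("geostat", "car"):
            if field is None:
                raise ValueError(f"{self.kind} model requires a FieldStructure")
            if rows is None:
                if field.n != self.n:
                    raise ValueError(
                        "data rows and field plots disagree; pass `rows` "
                        "mapping data rows into the field layout"
                    )
                rows = np.arange(self.n)
            rows = np.asarray(rows, dtype=int)
            if rows.size != self.n:
                raise ValueError("rows must have one entry per observation")
        self.rows = rows
        self.band_names = (
            list(band_names) if band_names is not None
            else [f"x{j + 1}" for j in range(self.p)]
        )
        self.spike_slab = spike_slab if spike_slab is not None else SpikeSlabPrior()
        self.variance_prior = (
            variance_prior if variance_prior is not None else VariancePrior()
        )
        self.phi_prior = phi_prior if phi_prior is not None else self._default_phi_prior()
        self.select = bool(select)
        self.standardize = bool(standardize)
        if standardize and self.p:
            self._x_mean = self.X.mean(axis=0)
            sd = self.X.std(axis=0)
            self._x_sd = np.where(sd > 0, sd, 1.0)
        else:
            self._x_mean = np.zeros(self.p)
            self._x_sd = np.ones(self.p)
        self._Z = (self.X - self._x_mean) / self._x_sd

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dataset(cls, dataset, field=None, rows=None, bands=None, **kwargs):
        """Build from a :class:`~phospec.preprocess.RegressionDataset`.

        ``bands`` optionally restricts the design to a subset of band
        indices (used when refitting on a selected band set).
        """
        X = dataset.X
        names = [f"b{int(round(c))}" for c in dataset.band_centers]
        if bands is not None:
            bands = np.asarray(bands, dtype=int)
            X = X[:, bands]
            names = [names[j] for j in bands]
        return cls(dataset.y, X, field=field, rows=rows, band_names=names, **kwargs)

    def _default_phi_prior(self) -> PhiPrior | None:
        if self.kind == "geostat":
            return PhiPrior(0.0, 1.0)
        if self.kind == "car":
            return PhiPrior(*self.field.phi_support)
        return None

    # -- fitting -------------------------------------------------------------

    def fit(self, config: MCMCConfig | None = None, **kwargs) -> "MCMCResults":
        """Run the Gibbs sampler and return an :class:`MCMCResults`.

        Keyword arguments (``n_iter``, ``burn_in``, ``thin``, ``seed``,
        ``phi_proposal_sd``) override the default :class:`MCMCConfig`.
        """
        from .results import MCMCResults

        if config is None:
            config = MCMCConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config or keyword overrides, not both")
        chain = self._run_chain(config)
        return MCMCResults(model=self, config=config, **chain)

    # standardized-scale design with intercept column
    def _design(self) -> np.ndarray:
        return np.column_stack([np.ones(self.n), self._Z])

    def _coef_prior_arrays(self):
        p0, mu, nu = self.spike_slab.expand(self.p)
        q = self.p + 1
        p0_f = np.concatenate([[0.5], p0])
        mu_f = np.concatenate([[0.0], mu])
        nu_f = np.concatenate([[_INTERCEPT_NU], nu])
        selectable = np.concatenate(
            [[False], np.full(self.p, self.select)]
        ).astype(bool)
        return q, p0_f, mu_f, nu_f, selectable

    def _run_chain(self, cfg: MCMCConfig) -> dict:
        rng = np.random.default_rng(cfg.seed)
        n, y = self.n, self.y
        D = self._design()
        q, p0_f, mu_f, nu_f, selectable = self._coef_prior_arrays()
        alpha, eta = self.variance_prior.alpha, self.variance_prior.eta

        beta = np.zeros(q)
        beta[0] = float(y.mean())
        gamma_f = np.ones(q, dtype=np.int8)
        var_y = float(y.var()) or 1.0
        sigma2 = tau2 = var_y
        phi = self.phi_prior.midpoint if self.phi_prior is not None else 0.0
        w = np.zeros(n)
        proposal_sd = cfg.phi_proposal_sd
        accept = total_mh = 0
        window_accept = window_total = 0

        state = self._prepare(D, y)

        n_kept = cfg.n_kept
        keep_intercept = np.empty(n_kept)
        keep_beta = np.empty((n_kept, self.p))
        keep_gamma = np.empty((n_kept, self.p), dtype=np.int8)
        keep_dev = np.empty(n_kept)
        keep_sigma2 = np.empty(n_kept) if self.kind in ("independent", "geostat") else None
        keep_tau2 = np.empty(n_kept) if self.kind in ("geostat", "car") else None
        keep_phi = np.empty(n_kept) if self.kind in ("geostat", "car") else None
        keep_w = np.empty((n_kept, n)) if self.kind == "geostat" else None
        k = 0

        for it in range(cfg.n_iter):
            # --- beta / gamma sweep ---
            G, g, obs_prec = self._gram(state, D, y, beta, w, sigma2, tau2, phi)
            order = rng.permutation(q)
            u_draws = rng.random(q)
            z_draws = rng.standard_normal(q)
            sweep_coefficients(
                G, g, beta, gamma_f, obs_prec,
                p0_f, mu_f, nu_f, selectable, order, u_draws, z_draws,
            )

            # --- variances, phi, latent field ---
            resid = y - D @ beta
            if self.kind == "independent":
                sigma2 = update_variance(rng, alpha, eta, n, float(resid @ resid))
            elif self.kind == "geostat":
                r_eps = resid - w
                tau2 = update_variance(rng, alpha, eta, n, float(r_eps @ r_eps))
                Hinv_w, logdet_H = self._geo_solve(state, phi, w)
                sigma2 = update_variance(rng, alpha, eta, n, float(w @ Hinv_w))

                def log_target(ph, _s=state, _w=w, _s2=sigma2):
                    return self._geo_phi_target(_s, ph, _w, _s2)

                cur = -0.5 * logdet_H - 0.5 * float(w @ Hinv_w) / sigma2
                phi, acc, _ = update_phi_mh(
                    phi, log_target, self.phi_prior.lo, self.phi_prior.hi,
                    proposal_sd, rng, current_log_target=cur,
                )
                accept += acc
                window_accept += acc
                total_mh += 1
                window_total += 1
                H = self._geo_H(state, phi)
                w = update_w(resid, H, sigma2, tau2, rng, cond_threshold=np.inf)
            else:  # car
                d_sub, M_sub = state["d_sub"], state["M_sub"]
                quad = car_quadform(resid, d_sub, M_sub, phi)
                tau2 = update_variance(rng, alpha, eta, n, quad)
                rdr = float(resid @ (d_sub * resid))
                rMr = float(resid @ (M_sub @ resid))

                def log_target(ph, _rdr=rdr, _rMr=rMr, _t2=tau2):
                    ld = self._car_logdet(state, ph)
                    return 0.5 * ld - 0.5 * (_rdr - ph * _rMr) / _t2

                phi, acc, _ = update_phi_mh(
                    phi, log_target, self.phi_prior.lo, self.phi_prior.hi,
                    proposal_sd, rng,
                )
                accept += acc
                window_accept += acc
                total_mh += 1
                window_total += 1

            # --- proposal adaptation during burn-in only ---
            if (
                cfg.adapt_phi
                and self.kind in ("geostat", "car")
                and it < cfg.burn_in
                and window_total >= 50
            ):
                rate = window_accept / window_total
                if rate < 0.20:
                    proposal_sd *= 0.8
                elif rate > 0.50:
                    proposal_sd *= 1.25
                window_accept = window_total = 0

            # --- record ---
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                dev = self._deviance(state, D, y, beta, w, sigma2, tau2, phi)
                if not np.isfinite(dev):
                    raise RuntimeError(
                        f"non-finite deviance at iteration {it}; chain diverged"
                    )
                keep_intercept[k] = beta[0]
                keep_beta[k] = beta[1:]
                keep_gamma[k] = gamma_f[1:]
                keep_dev[k] = dev
                if keep_sigma2 is not None:
                    keep_sigma2[k] = sigma2
                if keep_tau2 is not None:
                    keep_tau2[k] = tau2
                if keep_phi is not None:
                    keep_phi[k] = phi
                if keep_w is not None:
                    keep_w[k] = w
                k += 1

        samples_std = PosteriorSamples(
            intercept=keep_intercept[:k],
            beta=keep_beta[:k],
            gamma=keep_gamma[:k],
            deviance=keep_dev[:k],
            sigma2=keep_sigma2[:k] if keep_sigma2 is not None else None,
            tau2=keep_tau2[:k] if keep_tau2 is not None else None,
            phi=keep_phi[:k] if keep_phi is not None else None,
            w=keep_w[:k] if keep_w is not None else None,
        )
        return {
            "samples_std": samples_std,
            "accept_rate": (accept / total_mh) if total_mh else None,
            "proposal_sd_final": proposal_sd if total_mh else None,
        }

    # -- kind-specific machinery --------------------------------------------

    def _prepare(self, D: np.ndarray, y: np.ndarray) -> dict:
        state: dict = {}
        if self.kind in ("independent", "geostat"):
            state["G"] = D.T @ D
            state["Dty"] = D.T @ y
        if self.kind == "geostat":
            coords = self.field.coords[self.rows]
            state["dist"] = euclidean_distances(coords)
            state["H_cache"] = {}
        if self.kind == "car":
            rows = self.rows
            d_sub = self.field.d_m[rows]
            M_sub = self.field.M[np.ix_(rows, rows)]
            state["d_sub"] = d_sub
            state["M_sub"] = M_sub
            state["P1"] = D.T @ (d_sub[:, None] * D)
            state["P2"] = D.T @ (M_sub @ D)
            state["u1"] = D.T @ (d_sub * y)
            state["u2"] = D.T @ (M_sub @ y)
            state["full_field"] = (
                rows.size == self.field.n and np.array_equal(np.sort(rows), rows)
                and np.array_equal(rows, np.arange(self.field.n))
            )
        return state

    def _gram(self, state, D, y, beta, w, sigma2, tau2, phi):
        """Return (G, g, obs_prec) for the coefficient sweep."""
        if self.kind == "independent":
            G = state["G"]
            g = state["Dty"] - G @ beta
            return G, g, 1.0 / sigma2
        if self.kind == "geostat":
            G = state["G"]
            g = (state["Dty"] - D.T @ w) - G @ beta
            return G, g, 1.0 / tau2
        G = state["P1"] - phi * state["P2"]
        g = (state["u1"] - phi * state["u2"]) - G @ beta
        return G, g, 1.0 / tau2

    def _geo_H(self, state, phi: float) -> np.ndarray:
        H = exp_correlation(state["dist"], phi) if phi > 0 else np.ones_like(state["dist"])
        H = H + _H_JITTER * np.eye(H.shape[0])
        return H

    def _geo_factor(self, state, phi: float):
        cache = state["H_cache"]
        if cache.get("phi") != phi:
            H = self._geo_H(state, phi)
            cf = cho_factor(H, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            cache.update(phi=phi, cf=cf, logdet=logdet)
        return cache["cf"], cache["logdet"]

    def _geo_solve(self, state, phi: float, w: np.ndarray):
        cf, logdet = self._geo_factor(state, phi)
        return cho_solve(cf, w), logdet

    def _geo_phi_target(self, state, phi: float, w: np.ndarray, sigma2: float) -> float:
        """log N(w | 0, sigma2 H(phi)) up to terms free of phi."""
        try:
            H = self._geo_H(state, phi)
            cf = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return -0.5 * logdet - 0.5 * float(w @ cho_solve(cf, w)) / sigma2

    def _car_logdet(self, state, phi: float) -> float:
        if state["full_field"]:
            return car_logdet(self.field.d_m, self.field.eigenvalues, phi)
        A = np.diag(state["d_sub"]) - phi * state["M_sub"]
        try:
            cf = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        return 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

    def _deviance(self, state, D, y, beta, w, sigma2, tau2, phi) -> float:
        """-2 log-likelihood at the given state (the DIC focus).

        The correlogram model uses the likelihood conditional on the
        latent field w, so its DIC effective-parameter count includes w.
        """
        resid = y - D @ beta
        if self.kind == "independent":
            return -2.0 * gaussian_loglik(resid, sigma2)
        if self.kind == "geostat":
            return -2.0 * gaussian_loglik(resid - w, tau2)
        ld = self._car_logdet(state, phi)
        return -2.0 * loglik_car(resid, tau2, state["d_sub"], state["M_sub"], phi, ld)

    def deviance_at(self, intercept, beta_std, sigma2=None, tau2=None, phi=None, w=None) -> float:
        """Deviance at a parameter point (standardized-scale coefficients)."""
        D = self._design()
        state = self._prepare(D, self.y)
        beta_full = np.concatenate([[intercept], beta_std])
        w_arr = np.zeros(self.n) if w is None else np.asarray(w, float)
        return self._deviance(
            state, D, self.y, beta_full, w_arr,
            sigma2 if sigma2 is not None else 1.0,
            tau2 if tau2 is not None else 1.0,
            phi if phi is not None else 0.0,
        )


class IndependentModel(BaseSpectralModel):
    """Model 1: independent-errors spike-and-slab regression."""

    kind = "independent"


class GeostatModel(BaseSpectralModel):
    """Model 2: latent Gaussian field with exponential correlogram + nugget."""

    kind = "geostat"


class CARModel(BaseSpectralModel):
    """Model 3: conditionally autoregressive joint model on the plot graph."""

    kind = "car"


_CLASSES = {
    "independent": IndependentModel,
    "geostat": GeostatModel,
    "car": CARModel,
}


def make_model(kind: str, *args, **kwargs) -> BaseSpectralModel:
    if kind not in _CLASSES:
        raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    return _CLASSES[kind](*args, **kwargs)


def fit_model(kind: str, y, X, field=None, config: MCMCConfig | None = None, **model_kwargs):
    """One-call convenience: build the model of the given kind and fit it."""
    model = make_model(kind, y, X, field=field, **model_kwargs)
    return model.fit(config=config if config is not None else MCMCConfig())


def loglik(kind: str, y, X, params: dict, fs: FieldStructure | None = None) -> float:
    """Log-likelihood of the data under one model kind at given parameters.

    ``params`` uses keys ``beta`` (length-p vector on the raw X scale,
    including no intercept unless X carries a constant column), plus the
    kind-appropriate subset of ``sigma2``, ``tau2``, ``phi``, ``w``.
    The CAR likelihood is evaluated through the eigenvalue identity for
    its determinant and a quadratic form — never an explicit inverse.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X @ np.asarray(params["beta"], dtype=float)
    if kind == "independent":
        return gaussian_loglik(y - mean, params["sigma2"])
    if kind == "geostat":
        return gaussian_loglik(y - mean - np.asarray(params["w"], float), params["tau2"])
    if kind == "car":
        if fs is None:
            raise ValueError("CAR likelihood requires a FieldStructure")
        phi, tau2 = params["phi"], params["tau2"]
        ld = car_logdet(fs.d_m, fs.eigenvalues, phi)
        return loglik_car(y - mean, tau2, fs.d_m, fs.M, phi, ld)
    raise ValueError(f"unknown model kind {kind!r}")
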
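"""Gibbs/Metropolis building blocks shared by the three models.

All conditional updates follow from the conjugate hierarchy: normal
likelihoods with a spike-and-slab normal mixture on coefficients give
Bernoulli/normal full conditionals for (gamma_j, beta_j); inverse-gamma
priors on variances stay inverse gamma; the spatial-dependence parameter
phi has no closed form and is updated by a random-walk Metropolis step on
a logit-transformed scale.

Conventions used throughout: the *observation precision structure* enters
the coefficient update through pre-accumulated Gram quantities
``G = X' P X`` and ``g = X' P r`` where ``P`` is the (possibly
non-diagonal) residual precision divided by its scalar variance, and
``r = y - X beta`` is the current residual.  This makes the identical
sweep serve the independent model (P = I / sigma2), the correlogram model
conditioned on the latent field (P = I / tau2), and the CAR model
(P = (D_M - phi M) / tau2).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

__all__ = [
    "sweep_coefficients",
    "draw_inverse_gamma",
    "update_variance",
    "update_phi_mh",
    "update_w",
    "gaussian_loglik",
    "car_quadform",
    "car_logdet",
    "loglik_car",
]

_LOG2PI = math.log(2.0 * math.pi)


def sweep_coefficients(
    G: np.ndarray,
    g: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    obs_prec: float,
    p0: np.ndarray,
    mu: np.ndarray,
    nu: np.ndarray,
    selectable: np.ndarray,
    order: np.ndarray,
    u_draws: np.ndarray,
    z_draws: np.ndarray,
) -> None:
    """One full conditional sweep over coefficients, in place.

    For each index ``j`` (visited in ``order``): the inclusion indicator
    gamma_j is drawn from its Bernoulli full conditional obtained by
    integrating beta_j out against the slab, then beta_j is drawn from its
    conditional normal if included, else set exactly to zero.
    Coefficients with ``selectable[j] = False`` (the intercept, or any
    refit with selection disabled) are always included.

    Parameters
    ----------
    G : (p, p) unscaled Gram matrix  X' A X  (A the correlation-precision)
    g : (p,) current  X' A r  with r the full residual; updated in place
    obs_prec : scalar 1/sigma2 (or 1/tau2) multiplying G and g
    u_draws, z_draws : per-coefficient uniform / standard-normal variates
    """
    G_diag = G.diagonal()
    for j in order:
        j = int(j)
        bj = beta[j]
        # x_j' P r_{-j}: add back this coefficient's own contribution
        a = (g[j] + G_diag[j] * bj) * obs_prec
        c = G_diag[j] * obs_prec + 1.0 / nu[j]
        m = (a + mu[j] / nu[j]) / c
        if selectable[j]:
            log_odds = (
                math.log((1.0 - p0[j]) / p0[j])
                - 0.5 * math.log(nu[j] * c)
                + 0.5 * (m * m * c - mu[j] * mu[j] / nu[j])
            )
            # P(gamma_j = 1 | rest) = sigmoid(log_odds)
            if log_odds > 0:
                include = u_draws[j] < 1.0 / (1.0 + math.exp(-log_odds))
            else:
                e = math.exp(log_odds)
                include = u_draws[j] < e / (1.0 + e)
        else:
            include = True
        new_b = m + z_draws[j] / math.sqrt(c) if include else 0.0
        delta = new_b - bj
        if delta != 0.0:
            g -= G[:, j] * delta
        beta[j] = new_b
        gamma[j] = 1 if include else 0


def draw_inverse_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    """One draw from IG(shape, rate): the reciprocal of Gamma(shape, rate)."""
    return float(rate / rng.gamma(shape))


def update_variance(
    rng: np.random.Generator,
    alpha: float,
    eta: float,
    n_terms: int,
    quad_form: float,
) -> float:
    """Inverse-gamma full conditional for a variance component.

    Posterior shape ``alpha + n/2`` and rate ``eta + quad/2`` where
    ``quad`` is the model-appropriate residual quadratic form (sum of
    squares for i.i.d. errors; ``r' (D_M - phi M) r`` for the CAR model;
    ``w' H(phi)^{-1} w`` for the latent geostatistical field).
    """
    if quad_form < 0:
        raise ValueError("residual quadratic form must be nonnegative")
    return draw_inverse_gamma(rng, alpha + 0.5 * n_terms, eta + 0.5 * quad_form)


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def update_phi_mh(
    phi: float,
    log_target,
    lo: float,
    hi: float,
    proposal_sd: float,
    rng: np.random.Generator,
    current_log_target: float | None = None,
):
    """Random-walk Metropolis step for phi on a logit-transformed scale.

    ``phi`` is mapped to the real line by z = logit((phi - lo)/(hi - lo));
    the proposal is z' = z + N(0, proposal_sd^2) and the acceptance ratio
    carries the Jacobian ``dphi/dz = (hi - lo) s(z) (1 - s(z))`` so the
    invariant distribution on the phi scale is exactly
    ``target(phi) * U(lo, hi)``.

    Returns ``(phi_new, accepted, log_target_at_new)``.
    """
    if not (lo < phi < hi):
        raise ValueError(f"phi={phi} outside support ({lo}, {hi})")
    if current_log_target is None:
        current_log_target = log_target(phi)
    if proposal_sd == 0.0:
        return phi, False, current_log_target
    width = hi - lo
    u = (phi - lo) / width
    z = _logit(u)
    z_new = z + proposal_sd * rng.standard_normal()
    u_new = _sigmoid(z_new)
    phi_new = lo + width * u_new
    if phi_new <= lo or phi_new >= hi:  # numerically saturated
        return phi, False, current_log_target
    new_log_target = log_target(phi_new)
    log_jac = math.log(u_new * (1.0 - u_new)) - math.log(u * (1.0 - u))
    log_ratio = new_log_target - current_log_target + log_jac
    if math.log(rng.random()) < log_ratio:
        return phi_new, True, new_log_target
    return phi, False, current_log_target


def update_w(
    resid: np.ndarray,
    H: np.ndarray,
    sigma2: float,
    tau2: float,
    rng: np.random.Generator,
    cond_threshold: float = 1e12,
) -> np.ndarray:
    """Draw the latent geostatistical field from its normal full conditional.

    With prior w ~ N(0, sigma2 H) and likelihood y - X beta = w + eps,
    eps ~ N(0, tau2 I), the conditional precision is
    ``H^{-1}/sigma2 + I/tau2`` and the conditional mean is the precision
    solve of ``resid / tau2`` (resid = y - X beta).  Sampling uses a
    Cholesky factorization throughout; no explicit inverses.
    """
    n = resid.size
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise np.linalg.LinAlgError(
            f"correlogram matrix ill-conditioned (cond={cond:.3e})"
        )
    H_cf = cho_factor(H, lower=True)
    # A = H^{-1}/sigma2 + I/tau2
    A = cho_solve(H_cf, np.eye(n)) / sigma2
    A[np.diag_indices(n)] += 1.0 / tau2
    L = cholesky(A, lower=True)
    mean = cho_solve((L, True), resid / tau2)
    z = rng.standard_normal(n)
    return mean + solve_triangular(L, z, lower=True, trans="T")


def gaussian_loglik(resid: np.ndarray, var: float) -> float:
    """Sum of independent N(0, var) log densities at the residuals."""
    resid = np.asarray(resid, dtype=float)
    n = resid.size
    return -0.5 * (n * (_LOG2PI + math.log(var)) + float(resid @ resid) / var)


def car_quadform(resid: np.ndarray, d_m: np.ndarray, M: np.ndarray, phi: float) -> float:
    """``r' (D_M - phi M) r`` without forming the precision matrix."""
    return float(resid @ (d_m * resid) - phi * (resid @ (M @ resid)))


def car_logdet(d_m: np.ndarray, eigenvalues: np.ndarray, phi: float) -> float:
    """``log det(D_M - phi M)`` via the scaled-adjacency eigenvalues.

    ``D_M - phi M = D^{1/2} (I - phi D^{-1/2} M D^{-1/2}) D^{1/2}``, so the
    log determinant is ``sum log d_i + sum log(1 - phi lambda_i)``.  Valid
    only for the *full* field; principal submatrices need a factorization.
    """
    terms = 1.0 - phi * eigenvalues
    if np.any(terms <= 0):
        raise ValueError(f"phi={phi} makes the CAR precision non-positive-definite")
    return float(np.sum(np.log(d_m)) + np.sum(np.log(terms)))


def loglik_car(
    resid: np.ndarray,
    tau2: float,
    d_m: np.ndarray,
    M: np.ndarray,
    phi: float,
    logdet_A: float,
) -> float:
    """Joint CAR log likelihood log N(y | X beta, tau2 (D_M - phi M)^{-1}).

    ``logdet_A`` is log det(D_M - phi M) supplied by the caller (eigenvalue
    identity for the full field, Cholesky for a training subset).
    """
    n = resid.size
    quad = car_quadform(resid, d_m, M, phi)
    return 0.5 * (logdet_A - n * (_LOG2PI + math.log(tau2)) - quad / tau2)
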
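"""Posterior results container: summaries, DIC, selection, prediction.

``MCMCResults`` plays the role a results class plays in statsmodels: it
holds the thinned chains produced by ``Model.fit()``, exposes posterior
means and credible intervals, the deviance information criterion, the
band-selection summaries (posterior inclusion probabilities and the most
probable submodel), held-out prediction with model-appropriate spatial
borrowing, and persistence of the chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import PosteriorSamples
from .priors import MCMCConfig

__all__ = ["MCMCResults"]


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    m = x.size
    if m < 4 or np.ptp(x) == 0:
        return float(m)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[m - 1 :]
    acf = acf / acf[0]
    # sum paired autocorrelations while positive (Geyer's rule)
    s = 0.0
    t = 1
    while 2 * t < m:
        pair = acf[2 * t - 1] + acf[2 * t]
        if pair < 0:
            break
        s += pair
        t += 1
    return float(m / max(1.0, 1.0 + 2.0 * s))


class MCMCResults:
    """Fitted-chain container returned by ``Model.fit``."""

    def __init__(self, model, config: MCMCConfig, samples_std: PosteriorSamples,
                 accept_rate=None, proposal_sd_final=None) -> None:
        self.model = model
        self.config = config
        self._std = samples_std
        self.accept_rate = accept_rate
        self.proposal_sd_final = proposal_sd_final
        self._samples_raw: PosteriorSamples | None = None

    # -- chains ---------------------------------------------------------------

    @property
    def samples(self) -> PosteriorSamples:
        """Draws with coefficients back-transformed to the raw X scale.

        Standardization is a linear reparametrization: a standardized
        coefficient b maps to b / sd on the raw scale, and its centering
        contribution folds into the intercept.  Exact zeros stay zero, so
        the gamma/beta sparsity correspondence survives the transform.
        """
        if self._samples_raw is None:
            s = self._std
            sd = self.model._x_sd
            mean = self.model._x_mean
            beta_raw = s.beta / sd
            intercept_raw = s.intercept - s.beta @ (mean / sd)
            self._samples_raw = PosteriorSamples(
                intercept=intercept_raw,
                beta=beta_raw,
                gamma=s.gamma,
                deviance=s.deviance,
                sigma2=s.sigma2,
                tau2=s.tau2,
                phi=s.phi,
                w=s.w,
            )
        return self._samples_raw

    @property
    def n_draws(self) -> int:
        return self._std.n_draws

    @property
    def deviance(self) -> np.ndarray:
        return self._std.deviance

    # -- point estimates ------------------------------------------------------

    @property
    def pip(self) -> np.ndarray:
        """Posterior inclusion probability per band: mean of gamma_j."""
        return self._std.gamma.mean(axis=0)

    @property
    def beta_mean(self) -> np.ndarray:
        """Posterior mean coefficients on the raw X scale (zeros included)."""
        return self.samples.beta.mean(axis=0)

    @property
    def intercept_mean(self) -> float:
        return float(self.samples.intercept.mean())

    def posterior_means(self) -> dict:
        out = {"intercept": self.intercept_mean, "beta": self.beta_mean}
        for name in ("sigma2", "tau2", "phi"):
            arr = getattr(self._std, name)
            if arr is not None:
                out[name] = float(arr.mean())
        if self._std.w is not None:
            out["w"] = self._std.w.mean(axis=0)
        return out

    # -- model fit ------------------------------------------------------------

    def deviance_at_posterior_mean(self) -> float:
        s = self._std
        return self.model.deviance_at(
            intercept=float(s.intercept.mean()),
            beta_std=s.beta.mean(axis=0),
            sigma2=float(s.sigma2.mean()) if s.sigma2 is not None else None,
            tau2=float(s.tau2.mean()) if s.tau2 is not None else None,
            phi=float(s.phi.mean()) if s.phi is not None else None,
            w=s.w.mean(axis=0) if s.w is not None else None,
        )

    def dic(self):
        """Deviance information criterion summary for this fit."""
        from .evaluation import compute_dic

        return compute_dic(
            self.deviance,
            self.deviance_at_posterior_mean(),
            point_estimates=self.posterior_means(),
        )

    def selection_summary(self, threshold: float = 0.6):
        from .evaluation import selection_summary

        return selection_summary(
            self._std.gamma, band_names=self.model.band_names, threshold=threshold
        )

    # -- prediction -----------------------------------------------------------

    def predict(self, X_new: np.ndarray, test_rows: np.ndarray | None = None) -> np.ndarray:
        """Plug-in posterior-mean prediction for new plots.

        For the independent model this is ``X_new beta_hat``.  The spatial
        models additionally borrow strength from the training plots:
        the correlogram model kriges the latent field to the test plots,
        the CAR model adds the conditional mean of the joint normal given
        the training residuals.  ``test_rows`` indexes the new plots into
        the model's FieldStructure (required for spatial kinds).
        """
        from .evaluation import predict_heldout

        return predict_heldout(self, X_new, test_rows)

    # -- reporting ------------------------------------------------------------

    def scalar_chains(self) -> dict:
        out = {"deviance": self._std.deviance}
        for name in ("sigma2", "tau2", "phi"):
            arr = getattr(self._std, name)
            if arr is not None:
                out[name] = arr
        return out

    def diagnostics(self) -> pd.DataFrame:
        """Posterior mean, sd, 95% interval and ESS per scalar parameter."""
        rows = []
        chains = {"intercept": self.samples.intercept, **self.scalar_chains()}
        for name, arr in chains.items():
            lo, hi = np.quantile(arr, [0.025, 0.975])
            rows.append(
                {
                    "parameter": name,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                    "q2.5": float(lo),
                    "q97.5": float(hi),
                    "ess": round(_ess(arr), 1),
                }
            )
        return pd.DataFrame(rows)

    def summary(self, threshold: float = 0.6) -> str:
        """Human-readable fit summary."""
        sel = self.selection_summary(threshold)
        fit = self.dic()
        lines = [
            f"{type(self.model).__name__} (kind={self.model.kind})",
            f"  n = {self.model.n}, bands = {self.model.p}, "
            f"draws = {self.n_draws}",
            f"  DIC = {fit.dic:.2f}  (Dbar = {fit.dbar:.2f}, p_D = {fit.p_d:.2f})",
        ]
        if self.accept_rate is not None:
            lines.append(f"  phi MH acceptance = {self.accept_rate:.2f}")
        lines.append(
            f"  bands with PIP >= {threshold}: "
            f"{len(sel.selected_threshold)} of {self.model.p}"
        )
        lines.append(
            f"  most probable submodel: {int(sel.avgmod.sum())} bands "
            f"(posterior frequency {sel.avgmod_freq:.3f})"
        )
        lines.append(self.diagnostics().to_string(index=False))
        return "\n".join(lines)

    def plot_trace(self, params=None, axes=None):
        """Trace plots for the scalar chains (matplotlib)."""
        import matplotlib.pyplot as plt

        chains = self.scalar_chains()
        if params is not None:
            chains = {k: v for k, v in chains.items() if k in params}
        if axes is None:
            _, axes = plt.subplots(len(chains), 1, figsize=(8, 2 * len(chains)))
        axes = np.atleast_1d(axes)
        for ax, (name, arr) in zip(axes, chains.items()):
            ax.plot(arr, lw=0.5)
            ax.axhline(arr.mean(), color="red", lw=1)
            ax.set_ylabel(name)
        return axes

    def plot_pip(self, threshold: float = 0.6, ax=None):
        """Posterior inclusion probability per band center."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.scatter(range(self.model.p), self.pip, s=8)
        ax.axhline(threshold, color="blue", lw=1)
        ax.set_xlabel("band")
        ax.set_ylabel("PIP")
        ax.set_ylim(-0.02, 1.02)
        return ax

    # -- persistence ----------------------------------------------------------

    def save(self, prefix) -> None:
        """Persist kept draws as CSV plus a JSON sidecar with metadata."""
        prefix = str(prefix)
        s = self.samples
        frame = pd.DataFrame(s.beta, columns=self.model.band_names)
        frame.insert(0, "intercept", s.intercept)
        for name in ("sigma2", "tau2", "phi"):
            arr = getattr(s, name)
            if arr is not None:
                frame[name] = arr
        frame["deviance"] = s.deviance
        for j, name in enumerate(self.model.band_names):
            frame[f"gamma_{name}"] = s.gamma[:, j]
        frame.to_csv(prefix + "_chains.csv", index=False)
        meta = {
            "kind": self.model.kind,
            "n": self.model.n,
            "p": self.model.p,
            "config": {
                "n_iter": self.config.n_iter,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "seed": self.config.seed,
                "phi_proposal_sd": self.config.phi_proposal_sd,
            },
            "accept_rate": self.accept_rate,
            "ess": {
                name: _ess(arr) for name, arr in self.scalar_chains().items()
            },
        }
        with open(prefix + "_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
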
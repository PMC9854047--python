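"""End-to-end orchestration: preprocess, fit, select, evaluate, compare.

``run_pipeline`` drives the full analysis for each year of data: resample
spectra to the 101-band grid, fit the three models with band selection on
all bands, refit on the two selected band sets (PIP threshold and the
most probable submodel) with selection disabled, compute DIC for every
model x criterion cell, score repeated-holdout predictive correlations on
shared splits, compute the five vegetation-index baselines on the same
splits, and report the percentage-point gap between the CAR model and the
index average.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (
    compare_to_indices,
    cv_split,
    run_cv,
    selection_summary,
)
from .indices import INDEX_NAMES, index_cv_correlations
from .models import MODEL_KINDS, make_model
from .preprocess import (
    assemble_dataset,
    default_band_centers,
    filter_window,
    read_phenotypes,
    read_spectra,
    resample_bsplines,
)
from .priors import MCMCConfig, SpikeSlabPrior
from .simulate import EmulationConfig, default_trial_layout, simulate_field_trial
from .spatial import build_layout

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "EvaluationReport", "run_pipeline"]

CRITERIA = ("all_bands", "pip_0.6", "avgmod")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-serializable)."""

    emulate: bool = False
    spectra_path: str | None = None
    pheno_path: str | None = None
    years: list | None = None
    outdir: str = "phospec_out"
    seed: int = 0
    # preprocessing
    window: tuple = (450.0, 850.0)
    band_step: float = 4.0
    # field layout
    layout_rows: int = 21
    layout_cols: int = 6
    plot_dx: float = 3.2
    plot_dy: float = 5.0
    adjacency: str = "rook"
    # MCMC
    n_iter: int = 100_000
    burn_in: int = 50_000
    thin: int = 5
    phi_proposal_sd: float = 0.25
    # priors
    p0: float = 0.9
    slab_nu: float = 1.0
    # selection / CV
    pip_threshold: float = 0.6
    n_test: int = 25
    cv_repeats: int = 5
    canonical_savi: bool = False
    model_kinds: tuple = MODEL_KINDS

    def __post_init__(self) -> None:
        if self.emulate == (self.spectra_path is not None):
            raise ValueError("set exactly one of --emulate or input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        out = {}
        for key, val in self.__dict__.items():
            out[key] = list(val) if isinstance(val, tuple) else val
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def mcmc(self, seed_offset: int = 0) -> MCMCConfig:
        return MCMCConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed + seed_offset,
            phi_proposal_sd=self.phi_proposal_sd,
        )


@dataclass
class EvaluationReport:
    """Tables produced by one pipeline run."""

    dic_table: pd.DataFrame       # rows: model, columns: (criterion, year)
    cv_table: pd.DataFrame        # mean held-out Pearson r, same shape
    index_table: pd.DataFrame     # rows: index, columns: year
    deltas: dict                  # year -> CAR-vs-index gap, percentage points
    selections: dict              # (year, model) -> SelectionSummary
    meta: dict = dc_field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dic_table.to_csv(outdir / "dic_table.csv", float_format="%.6g")
        self.cv_table.to_csv(outdir / "cv_table.csv", float_format="%.6g")
        self.index_table.to_csv(outdir / "index_table.csv", float_format="%.6g")
        summary = {
            "meta": self.meta,
            "car_vs_index_pp": self.deltas,
            "selected_bands": {
                f"{year}/{model}": sel.selected_threshold
                for (year, model), sel in self.selections.items()
            },
            "avgmod_bands": {
                f"{year}/{model}": [
                    sel.band_names[j] for j in sel.avgmod_indices
                ]
                for (year, model), sel in self.selections.items()
            },
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


def _prepare_year(cfg: RunConfig, raw, pheno_year, fs):
    lo, hi = cfg.window
    centers = default_band_centers(lo, hi, cfg.band_step)
    windowed = filter_window(raw, lo, hi)
    spectra = resample_bsplines(windowed, centers)
    # field layout order: plots appear in fs order
    order = [pid for pid in fs.plot_ids if pid in set(pheno_year["plot_id"])]
    return assemble_dataset(spectra, pheno_year, plot_order=order), spectra


def _criterion_bands(summary, threshold_sel: bool):
    idx = summary.selected_indices if threshold_sel else summary.avgmod_indices
    return np.asarray(idx, dtype=int)


def run_pipeline(cfg: RunConfig) -> EvaluationReport:
    """Run the full analysis described in the module docstring."""
    if cfg.emulate:
        emu = EmulationConfig(
            seed=cfg.seed,
            layout_rows=cfg.layout_rows,
            layout_cols=cfg.layout_cols,
        )
        raw, pheno, fs = simulate_field_trial(emu)
    else:
        raw = read_spectra(cfg.spectra_path)
        pheno = read_phenotypes(cfg.pheno_path)
        fs = build_layout(
            cfg.layout_rows, cfg.layout_cols, cfg.plot_dx, cfg.plot_dy,
            n_plots=pheno["plot_id"].nunique(), adjacency=cfg.adjacency,
        )
    years = cfg.years if cfg.years else sorted(pheno["year"].unique())
    prior = SpikeSlabPrior(p0=cfg.p0, nu=cfg.slab_nu)

    dic_cells: dict = {}
    cv_cells: dict = {}
    index_cells: dict = {}
    deltas: dict = {}
    selections: dict = {}

    for year in years:
        pheno_year = pheno[pheno["year"] == year].reset_index(drop=True)
        dataset, spectra = _prepare_year(cfg, raw, pheno_year, fs)
        splits = cv_split(dataset.n, cfg.n_test, cfg.cv_repeats, seed=cfg.seed)
        for m_i, kind in enumerate(cfg.model_kinds):
            logger.info("year %s: fitting %s (all bands)", year, kind)
            spatial = kind in ("geostat", "car")
            full = make_model(
                kind, dataset.y, dataset.X,
                field=fs if spatial else None,
                band_names=[f"b{int(c)}" for c in dataset.band_centers],
                spike_slab=prior,
            ).fit(config=cfg.mcmc(seed_offset=m_i))
            sel = full.selection_summary(cfg.pip_threshold)
            selections[(year, kind)] = sel
            dic_cells[(kind, "all_bands", year)] = full.dic().dic
            cv_cells[(kind, "all_bands", year)] = run_cv(
                kind, dataset, fs if spatial else None, splits,
                cfg.mcmc(seed_offset=m_i), spike_slab=prior,
            ).mean_r
            for criterion, bands in (
                ("pip_0.6", _criterion_bands(sel, True)),
                ("avgmod", _criterion_bands(sel, False)),
            ):
                logger.info(
                    "year %s: refitting %s on %d bands (%s)",
                    year, kind, bands.size, criterion,
                )
                refit = make_model(
                    kind, dataset.y, dataset.X[:, bands],
                    field=fs if spatial else None,
                    band_names=[f"b{int(dataset.band_centers[j])}" for j in bands],
                    select=False,
                ).fit(config=cfg.mcmc(seed_offset=10 + m_i))
                dic_cells[(kind, criterion, year)] = refit.dic().dic
                cv_cells[(kind, criterion, year)] = run_cv(
                    kind, dataset, fs if spatial else None, splits,
                    cfg.mcmc(seed_offset=10 + m_i), bands=bands, select=False,
                ).mean_r
        # vegetation-index baselines on the same splits
        for name in INDEX_NAMES:
            rep = index_cv_correlations(
                name, spectra, dataset.y, splits, canonical_savi=cfg.canonical_savi
            )
            index_cells[(name, year)] = rep["mean_r"]
        deltas[str(year)] = compare_to_indices(
            cv_cells[("car", "avgmod", year)],
            [index_cells[(name, year)] for name in INDEX_NAMES],
        ) if "car" in cfg.model_kinds else float("nan")

    dic_table = _grid(dic_cells, cfg.model_kinds, years)
    cv_table = _grid(cv_cells, cfg.model_kinds, years)
    index_table = pd.DataFrame(
        {year: [index_cells[(name, year)] for name in INDEX_NAMES] for year in years},
        index=list(INDEX_NAMES),
    )
    report = EvaluationReport(
        dic_table=dic_table,
        cv_table=cv_table,
        index_table=index_table,
        deltas=deltas,
        selections=selections,
        meta={"seed": cfg.seed, "config_hash": cfg.config_hash()},
    )
    return report


def _grid(cells: dict, kinds, years) -> pd.DataFrame:
    cols = pd.MultiIndex.from_product([CRITERIA, years], names=["criterion", "year"])
    table = pd.DataFrame(index=list(kinds), columns=cols, dtype=float)
    for (kind, criterion, year), val in cells.items():
        table.loc[kind, (criterion, year)] = val
    return table
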
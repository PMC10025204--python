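"""Gene-wise benchmark-concentration screening of an expression matrix.

The screen mirrors the standard transcriptomics BMC workflow: a one-way
ANOVA prefilter across concentration groups with Benjamini-Hochberg
correction, a nine-model continuous fit per surviving probe, BMC with
profile-likelihood bounds for the AIC-best model, a likelihood-ratio
goodness-of-fit p-value, and the signed maximum fold change used for
direction calls downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bmc_models import (
    MODEL_NAMES,
    ModelFit,
    compute_bmd_point,
    fit_model_suite,
    profile_bmd_bounds,
)
from .data import ExpressionDataset

__all__ = [
    "BMCConfig",
    "BMCScreen",
    "BMCScreenResults",
    "anova_prefilter",
    "fit_pvalue",
    "select_best_model",
    "max_fold_change",
    "compute_bmd",
]


@dataclass(frozen=True)
class BMCConfig:
    """Settings of the gene-wise screen.

    ``bmr_factor`` is the benchmark response; in the default ``sd`` mode
    it is a multiple of the modelled residual SD, in ``fold`` mode a
    linear-scale fold change (the alternative reading of the same
    number). ``alpha`` is the BH-adjusted ANOVA cutoff.
    """

    bmr_factor: float = 1.021
    bmr_mode: str = "sd"  # "sd" | "fold"
    alpha: float = 0.05
    level: float = 0.90
    models: tuple = MODEL_NAMES


def anova_prefilter(dataset: ExpressionDataset, alpha: float = 0.05):
    """One-way ANOVA across concentration groups with BH correction.

    Returns ``(kept_probe_ids, table)`` where the table carries the raw
    and BH-adjusted p-value per probe. Probes whose F statistic is
    undefined (within-group variance zero everywhere, or a lone sample in
    every group) are excluded with a warning. No fold-change filter is
    applied at this stage.
    """
    groups = dataset.concentration_groups()
    if len(groups) < 2:
        raise ValueError("need >=2 concentration groups for the ANOVA prefilter")
    idx_sets = list(groups.values())
    raw = np.full(dataset.n_probes, np.nan)
    for i in range(dataset.n_probes):
        samples = [dataset.values[i, idx] for idx in idx_sets]
        with np.errstate(invalid="ignore", divide="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*samples)
        raw[i] = p
    bad = ~np.isfinite(raw)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} probes had an undefined F statistic "
                      "and were excluded from the prefilter", stacklevel=2)
    table = pd.DataFrame({"probe_id": dataset.probe_ids, "p_raw": raw})
    ok = np.isfinite(raw)
    adj = np.full_like(raw, np.nan)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    table["p_adj"] = adj
    table["kept"] = np.isfinite(adj) & (adj < alpha)
    kept = set(table.loc[table["kept"], "probe_id"])
    return kept, table


def max_fold_change(concentrations, values):
    """Signed linear-scale fold change of the most-changed group vs control.

    Group means are taken on the log2 scale; the group with the largest
    |mean - control mean| defines the value, reported as
    ``sign * 2**|delta|`` (so no change is +1.0, a 1-log2 drop is -2.0).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(values, dtype=float)
    if not np.any(x == 0):
        raise ValueError("no control group (concentration 0) present")
    ctrl = y[x == 0].mean()
    best = 0.0
    for c in np.unique(x[x > 0]):
        delta = y[x == c].mean() - ctrl
        if abs(delta) > abs(best):
            best = delta
    if best == 0.0:
        return 1.0
    return float(np.sign(best) * 2 ** abs(best))


def fit_pvalue(fit: ModelFit, concentrations, values):
    """Likelihood-ratio goodness-of-fit against the saturated means model.

    2*(loglik_saturated - loglik_model) is referred to chi2 with
    df = n_groups - n_mean_params. Returns None when df <= 0 (the model is
    as rich as the group means).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(values, dtype=float)
    groups = np.unique(x)
    df = len(groups) - fit.n_mean_params
    if df <= 0:
        return None
    resid = y.copy()
    for c in groups:
        m = x == c
        resid[m] = y[m] - y[m].mean()
    rss = float(resid @ resid)
    n = y.size
    # a fit whose residuals sit at float precision is exact: no lack of fit
    rss_model = n * fit.sigma ** 2
    if rss_model <= n * (1e-8 * (np.std(y) + 1e-300)) ** 2:
        return 1.0
    ll_sat = -0.5 * n * (np.log(2 * np.pi * max(rss / n, 1e-30)) + 1.0)
    lr = max(0.0, 2 * (ll_sat - fit.loglik))
    return float(stats.chi2.sf(lr, df))


def select_best_model(fits: list[ModelFit]) -> ModelFit | None:
    """Lowest AIC among converged fits with a BMC.

    Ties break to fewer mean parameters, then to the fixed ordering of the
    nine model names. Returns None when nothing qualifies (the probe is
    dropped with that reason recorded by the caller).
    """
    order = {name: i for i, name in enumerate(MODEL_NAMES)}
    ok = [f for f in fits if f.converged and f.bmd is not None]
    if not ok:
        return None
    return min(ok, key=lambda f: (f.aic, f.n_mean_params,
                                  order.get(f.model_name, 99)))


def compute_bmd(fit: ModelFit, concentrations, values, max_dose,
                bmr_factor: float = 1.021, bmr_mode: str = "sd",
                level: float = 0.90):
    """BMC point estimate and profile-likelihood BMDL/BMDU for one fit."""
    bmd, _ = compute_bmd_point(fit, max_dose, bmr_factor, bmr_mode)
    if bmd is None:
        return None, None, None
    fit.bmd = bmd
    bmdl, bmdu = profile_bmd_bounds(fit, concentrations, values, max_dose,
                                    bmr_factor, bmr_mode, level)
    return bmd, bmdl, bmdu


class BMCScreenResults:
    """Per-probe outcome of the gene-wise BMC screen.

    ``frame`` has one row per probe that passed the ANOVA prefilter and
    produced a usable best model: probe_id, best_model, bmd, bmdl, bmdu,
    fit_p, max_fc, direction. ``dropped`` maps probe_id -> reason for
    probes lost after the prefilter; ``anova_table`` records the
    prefilter itself.
    """

    def __init__(self, screen, frame, anova_table, dropped, fits):
        self.screen = screen
        self.frame = frame
        self.anova_table = anova_table
        self.dropped = dropped
        self._fits = fits

    @property
    def config(self) -> BMCConfig:
        return self.screen.config

    def fits_for(self, probe_id: str) -> list[ModelFit]:
        return self._fits[probe_id]

    def summary(self) -> str:
        n_pass = int(self.anova_table["kept"].sum())
        lines = [
            "Gene-wise benchmark-concentration screen",
            f"  probes: {len(self.anova_table)}  "
            f"passed ANOVA+BH (alpha={self.config.alpha}): {n_pass}  "
            f"with BMC: {len(self.frame)}  dropped: {len(self.dropped)}",
            f"  BMR: {self.config.bmr_factor} ({self.config.bmr_mode} mode)",
        ]
        if len(self.frame):
            med = self.frame["bmd"].median()
            lines.append(f"  median BMC of fitted probes: {med:.4g} uM")
            counts = self.frame["best_model"].value_counts()
            lines.append("  best-model counts: "
                         + ", ".join(f"{k}={v}" for k, v in counts.items()))
        return "\n".join(lines)


class BMCScreen:
    """Model object for the gene-wise BMC analysis of one expression matrix."""

    def __init__(self, dataset: ExpressionDataset, config: BMCConfig | None = None):
        self.dataset = dataset
        self.config = config or BMCConfig()

    def fit(self, probe_ids=None) -> BMCScreenResults:
        """Run prefilter, model suite, BMC and bounds for every probe.

        ``probe_ids`` restricts the screen (the prefilter still runs on
        the full matrix, as the BH correction is matrix-wide).
        """
        ds, cfg = self.dataset, self.config
        kept, anova_table = anova_prefilter(ds, cfg.alpha)
        if probe_ids is not None:
            kept = kept & set(probe_ids)
        x = ds.concentrations
        max_dose = float(x.max())
        rows, dropped, fits_by_probe = [], {}, {}
        for i, pid in enumerate(ds.probe_ids):
            if pid not in kept:
                continue
            y = ds.values[i]
            fits = fit_model_suite(x, y, cfg.models)
            for f in fits:
                f.bmd, _ = compute_bmd_point(f, max_dose, cfg.bmr_factor,
                                             cfg.bmr_mode)
            fits_by_probe[pid] = fits
            best = select_best_model(fits)
            if best is None:
                dropped[pid] = "no converged model reached the benchmark response"
                continue
            best.bmdl, best.bmdu = profile_bmd_bounds(
                best, x, y, max_dose, cfg.bmr_factor, cfg.bmr_mode, cfg.level)
            best.fit_p = fit_pvalue(best, x, y)
            mfc = max_fold_change(x, y)
            rows.append(dict(
                probe_id=pid, best_model=best.model_name, bmd=best.bmd,
                bmdl=best.bmdl, bmdu=best.bmdu, fit_p=best.fit_p,
                max_fc=mfc, direction="up" if mfc >= 0 else "down"))
        frame = pd.DataFrame(
            rows, columns=["probe_id", "best_model", "bmd", "bmdl", "bmdu",
                           "fit_p", "max_fc", "direction"])
        return BMCScreenResults(self, frame, anova_table, dropped, fits_by_probe)
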
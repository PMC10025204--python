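"""Synthetic concentration-response data with known ground truth.

Two generators mirror the study design so that every pipeline stage can
be exercised and calibrated without external data:

* :func:`simulate_endpoint_table` draws endpoint readouts (AdipoRed /
  qPCR style) from the same exponential parallel-curve model the RPF
  engine fits — per-experiment backgrounds, per-substance potency set by
  a true RPF vector, shared shape, lognormal response noise, three
  independent experiments by default.
* :func:`simulate_expression_matrix` builds a probes x samples log2
  matrix over the control + 6.25...400 uM concentration grid with three
  samples per concentration, embedding regulated gene sets whose genes
  follow a Hill-shaped log2 shift (deliberately not the RPF engine's
  exponential, so the estimators are not validated only against their own
  generating model) with per-gene benchmark concentrations drawn from a
  lognormal, plus configurable fractions of promiscuous and
  direction-conflicting probes to exercise the quality filters.

All randomness flows from the single ``seed`` of each config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DoseResponseTable, ExpressionDataset, GeneSetCatalog, ProbeAnnotation
from .exponential import exp_model_predict

__all__ = [
    "EndpointSimConfig",
    "ExpressionSimConfig",
    "simulate_endpoint_table",
    "simulate_expression_matrix",
]

_GRID = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0)


@dataclass(frozen=True)
class EndpointSimConfig:
    """Ground truth for one endpoint readout.

    ``rpfs`` maps substance -> true RPF; the index substance must carry
    exactly 1. Potencies are ``b_s = index_b / RPF_s``. Backgrounds are
    per substance x experiment: ``base_background`` times a lognormal
    shift with SD ``background_shift_sd`` (the between-experiment
    heterogeneity the covariate on ``a`` absorbs). ``sigma`` is the
    residual SD of log responses, per substance.

    ``concentration_grids`` optionally overrides the common grid per
    substance, mirroring how the maximum tested concentration is set per
    substance in practice (solubility and the viability ceiling);
    :meth:`range_found` builds the potency-adapted version, each
    substance's grid scaled to its own active range.
    """

    rpfs: dict = field(default_factory=lambda: {"PFOA": 1.0, "S-LOW": 0.1,
                                                "S-HIGH": 10.0})
    index_substance: str = "PFOA"
    index_b: float = 50.0
    c: float = 2.0
    d: float = 1.0
    base_background: float = 100.0
    background_shift_sd: float = 0.3
    sigma: float = 0.15
    concentrations: tuple = _GRID
    concentration_grids: dict | None = None
    replicates: int = 3
    experiments: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.index_substance not in self.rpfs:
            raise ValueError("index substance missing from the RPF map")
        if self.rpfs[self.index_substance] != 1.0:
            raise ValueError("the index substance must have true RPF 1")
        if min(self.rpfs.values()) <= 0 or min(self.index_b, self.c, self.d) <= 0:
            raise ValueError("RPFs and model parameters must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.concentration_grids is not None:
            missing = set(self.rpfs) - set(self.concentration_grids)
            if missing:
                raise ValueError(f"no concentration grid for {sorted(missing)}")

    def grid_for(self, substance: str) -> tuple:
        if self.concentration_grids is not None:
            return tuple(self.concentration_grids[substance])
        return tuple(self.concentrations)

    @classmethod
    def range_found(cls, **kw) -> "EndpointSimConfig":
        """Config whose grids are scaled per substance to its potency.

        Emulates a dose-range-finding step: each substance is tested over
        the base grid divided by its RPF, so every curve is observed over
        the same region relative to its own potency.
        """
        cfg = cls(**kw)
        grids = {s: tuple(np.asarray(cfg.concentrations) / r)
                 for s, r in cfg.rpfs.items()}
        from dataclasses import replace
        return replace(cfg, concentration_grids=grids)


def simulate_endpoint_table(cfg: EndpointSimConfig):
    """Draw one endpoint table; returns ``(DoseResponseTable, truth)``.

    ``truth`` records every generating parameter: b per substance, the
    backgrounds per (substance, experiment), shared c and d, sigma and
    the RPF vector.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    truth_b = {s: cfg.index_b / r for s, r in cfg.rpfs.items()}
    truth_a = {}
    for s in sorted(cfg.rpfs):
        b = truth_b[s]
        for e in range(1, cfg.experiments + 1):
            exp_label = f"exp{e}"
            a = cfg.base_background * float(np.exp(
                rng.normal(0.0, cfg.background_shift_sd)))
            truth_a[(s, exp_label)] = a
            for x in cfg.grid_for(s):
                mean = exp_model_predict(a, b, cfg.c, cfg.d, x)
                eps = rng.normal(0.0, cfg.sigma, size=cfg.replicates)
                for r in range(cfg.replicates):
                    rows.append(dict(substance=s, experiment=exp_label,
                                     concentration=x,
                                     response=mean * float(np.exp(eps[r]))))
    table = DoseResponseTable(pd.DataFrame(rows))
    truth = dict(b_s=truth_b, a_se=truth_a, c=cfg.c, d=cfg.d,
                 sigma=cfg.sigma, rpfs=dict(cfg.rpfs),
                 index=cfg.index_substance)
    return table, truth


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Ground truth for a probes x samples log2 expression matrix.

    ``n_sets`` disjoint gene sets of ``set_size`` genes are carved from
    the platform; the first ``n_regulated_sets`` are regulated with
    alternating direction (up, down, up, ...). Each regulated gene's
    log2 shift follows ``effect * x**h / (x**h + K**h)`` with K drawn
    lognormal(``bmc_median``, ``bmc_log_gsd``); unregulated probes are
    baseline plus noise. ``promiscuous_fraction`` of probes get a second
    gene assignment, and ``conflicting_fraction`` of regulated genes get
    an extra probe shifted the opposite way.
    """

    n_probes: int = 200
    concentrations: tuple = _GRID
    replicates: int = 3
    n_sets: int = 10
    set_size: int = 10
    n_regulated_sets: int = 5
    effect_log2: float = 1.5
    bmc_median: float = 50.0
    bmc_log_gsd: float = 0.3
    hill_coef: float = 3.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    promiscuous_fraction: float = 0.03
    conflicting_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")
        if self.n_sets * self.set_size > self.n_probes:
            raise ValueError("gene sets exceed the number of platform genes")
        if self.n_regulated_sets > self.n_sets:
            raise ValueError("more regulated sets than sets in the catalog")


def _hill_shift(x, effect, bmc, h):
    with np.errstate(over="ignore"):
        xh = np.power(x, h)
        return effect * xh / (xh + bmc ** h)


def simulate_expression_matrix(cfg: ExpressionSimConfig):
    """Draw one matrix; returns ``(dataset, annotation, catalog, truth)``.

    ``truth`` records the regulated sets with their directions, the
    regulated genes with their true per-gene BMCs, and the probes planted
    as promiscuous or conflicting.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_probes)]
    probes = [f"P{i + 1:04d}" for i in range(cfg.n_probes)]
    mapping = {p: {g} for p, g in zip(probes, genes)}

    sets = {}
    for k in range(cfg.n_sets):
        members = genes[k * cfg.set_size:(k + 1) * cfg.set_size]
        sets[f"SET{k + 1:03d}"] = (f"Synthetic set {k + 1}", frozenset(members))
    catalog = GeneSetCatalog(sets)

    set_ids = sorted(sets)
    regulated_sets = {set_ids[k]: ("up" if k % 2 == 0 else "down")
                      for k in range(cfg.n_regulated_sets)}
    gene_dir: dict[str, str] = {}
    gene_bmc: dict[str, float] = {}
    for set_id, direction in regulated_sets.items():
        for g in sorted(catalog.members(set_id)):
            gene_dir[g] = direction
            gene_bmc[g] = float(np.exp(rng.normal(np.log(cfg.bmc_median),
                                                  cfg.bmc_log_gsd)))

    x = np.repeat(np.asarray(cfg.concentrations, dtype=float), cfg.replicates)
    labels = [f"c{ci}_r{r + 1}" for ci in range(len(cfg.concentrations))
              for r in range(cfg.replicates)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_probes)

    rows = []
    for i, (p, g) in enumerate(zip(probes, genes)):
        mean = np.full_like(x, baseline[i])
        if g in gene_dir:
            sgn = 1.0 if gene_dir[g] == "up" else -1.0
            mean = mean + sgn * _hill_shift(x, cfg.effect_log2, gene_bmc[g],
                                            cfg.hill_coef)
        rows.append(mean + rng.normal(0.0, cfg.noise_sd, size=x.size))
    values = np.vstack(rows)

    # promiscuous probes: a second gene assignment (drawn among unregulated
    # genes so the planting does not alter any set's regulated count)
    unreg = [g for g in genes if g not in gene_dir]
    n_prom = int(round(cfg.promiscuous_fraction * cfg.n_probes))
    prom_probes = list(rng.choice(probes, size=n_prom, replace=False)) if n_prom else []
    for p in prom_probes:
        extra = unreg[int(rng.integers(len(unreg)))]
        mapping[p] = mapping[p] | {extra}

    # conflicting probes: an extra opposite-direction probe for a fraction
    # of regulated genes (the 0.5 rule should then drop the gene)
    reg_genes = sorted(gene_dir)
    n_conf = int(round(cfg.conflicting_fraction * len(reg_genes)))
    conf_genes = list(rng.choice(reg_genes, size=n_conf, replace=False)) if n_conf else []
    extra_probes, extra_rows = [], []
    for j, g in enumerate(conf_genes):
        p = f"P{cfg.n_probes + j + 1:04d}c"
        sgn = -1.0 if gene_dir[g] == "up" else 1.0
        mean = (rng.normal(cfg.baseline_mean, cfg.baseline_sd)
                + sgn * _hill_shift(x, cfg.effect_log2, gene_bmc[g], cfg.hill_coef))
        extra_probes.append(p)
        extra_rows.append(mean + rng.normal(0.0, cfg.noise_sd, size=x.size))
        mapping[p] = {g}
    if extra_probes:
        probes = probes + extra_probes
        values = np.vstack([values, np.vstack(extra_rows)])

    dataset = ExpressionDataset(probes, labels, x, values)
    annotation = ProbeAnnotation(mapping)
    truth = dict(regulated_sets=regulated_sets, gene_direction=gene_dir,
                 gene_bmc=gene_bmc, promiscuous_probes=sorted(prom_probes),
                 conflicting_genes=sorted(conf_genes))
    return dataset, annotation, catalog, truth
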
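"""Gene-level quality filters and Fisher-exact gene-set (category) analysis.

Probe-level BMC results are reduced to genes through a chain of quality
filters (promiscuous probes, out-of-range or ill-determined BMCs, weak
fold changes, direction-conflicting probes), then each gene set of a
catalog is tested for enrichment of regulated genes with a two-tailed
Fisher exact test against the platform universe, and classified as up- or
downregulated when at least 60% of its regulated genes move that way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GeneSetCatalog, ProbeAnnotation

__all__ = [
    "FilterConfig",
    "GeneSetConfig",
    "GeneSetResult",
    "apply_gene_filters",
    "fisher_enrichment",
    "classify_direction",
    "summarize_sets",
    "run_gene_set_analysis",
]


@dataclass(frozen=True)
class FilterConfig:
    """Gene/probe quality filters applied before the category tests."""

    max_fit_p: float = 0.1          # remove BMC with goodness-of-fit p below this
    max_bmd_bmdl_ratio: float = 20.0
    max_bmdu_bmdl_ratio: float = 40.0
    min_abs_fold_change: float = 1.2
    conflict_minority_fraction: float = 0.5  # minority >= this => gene conflicting
    remove_promiscuous: bool = True


@dataclass(frozen=True)
class GeneSetConfig:
    """Category-level acceptance thresholds."""

    fisher_cutoff: float = 0.1
    min_regulated: int = 5
    min_pct_regulated: float = 20.0
    direction_threshold: float = 0.6


@dataclass
class GeneSetResult:
    """Summary of one gene set that passed the category filters."""

    set_id: str
    set_name: str
    n_members_on_platform: int
    n_regulated: int
    fisher_p_two_tail: float
    pct_regulated: float
    median_bmc: float
    n_up: int
    n_down: int
    direction_class: str  # up | down | mixed

    def as_dict(self):
        return self.__dict__.copy()


def apply_gene_filters(probe_table: pd.DataFrame, annotation: ProbeAnnotation,
                       max_dose: float, config: FilterConfig | None = None):
    """Reduce probe-level BMC rows to regulated genes.

    ``probe_table`` is the frame of :class:`~relpot.bmc.BMCScreenResults`
    (probe_id, bmd, bmdl, bmdu, fit_p, max_fc, direction). A probe
    survives when it maps to exactly one gene, its BMC is at or below the
    highest tested dose, its goodness-of-fit p is at least ``max_fit_p``
    (an absent p keeps the probe, with the count reported), BMD/BMDL and
    BMDU/BMDL stay within their ratio caps, and |max fold change| is at
    least 1.2. A gene whose surviving probes split in direction with a
    minority fraction at or above the conflict threshold is removed as
    conflicting.

    Returns ``(genes, report)``: a DataFrame with one row per regulated
    gene (gene, bmd = mean of surviving probes' BMCs, direction = majority
    direction, fold change = mean of probe fold changes, n_probes) and a
    dict of exclusion counts.
    """
    cfg = config or FilterConfig()
    report = dict(promiscuous=0, no_bmd=0, bmd_above_max_dose=0, poor_fit=0,
                  fit_p_missing_kept=0, wide_bmd_bmdl=0, wide_bmdu_bmdl=0,
                  weak_fold_change=0, conflicting_genes=0)
    surviving = []
    for row in probe_table.itertuples(index=False):
        genes = annotation.genes(row.probe_id)
        if not genes:
            continue
        if cfg.remove_promiscuous and len(genes) > 1:
            report["promiscuous"] += 1
            continue
        if row.bmd is None or not np.isfinite(row.bmd):
            report["no_bmd"] += 1
            continue
        if row.bmd > max_dose:
            report["bmd_above_max_dose"] += 1
            continue
        if row.fit_p is None or not np.isfinite(row.fit_p):
            report["fit_p_missing_kept"] += 1
        elif row.fit_p < cfg.max_fit_p:
            report["poor_fit"] += 1
            continue
        if row.bmdl and np.isfinite(row.bmdl) and row.bmdl > 0:
            if row.bmd / row.bmdl > cfg.max_bmd_bmdl_ratio:
                report["wide_bmd_bmdl"] += 1
                continue
            if (row.bmdu and np.isfinite(row.bmdu)
                    and row.bmdu / row.bmdl > cfg.max_bmdu_bmdl_ratio):
                report["wide_bmdu_bmdl"] += 1
                continue
        if abs(row.max_fc) < cfg.min_abs_fold_change:
            report["weak_fold_change"] += 1
            continue
        surviving.append(dict(gene=next(iter(genes)), bmd=float(row.bmd),
                              direction=row.direction, max_fc=float(row.max_fc)))
    if not surviving:
        return pd.DataFrame(columns=["gene", "bmd", "direction", "max_fc",
                                     "n_probes"]), report
    probes = pd.DataFrame(surviving)
    rows = []
    eps = 1e-9
    for gene, sub in probes.groupby("gene"):
        n_up = int((sub["direction"] == "up").sum())
        n_down = len(sub) - n_up
        if n_up and n_down:
            minority = min(n_up, n_down) / len(sub)
            if minority >= cfg.conflict_minority_fraction - eps:
                report["conflicting_genes"] += 1
                continue
        rows.append(dict(gene=gene, bmd=float(sub["bmd"].mean()),
                         direction="up" if n_up > n_down else "down",
                         max_fc=float(sub["max_fc"].mean()),
                         n_probes=len(sub)))
    return pd.DataFrame(rows), report


def fisher_enrichment(n_regulated_in_set: int, set_size: int,
                      n_regulated_total: int, universe_size: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 regulated-in-set table.

    The two-tailed p sums the probabilities of all hypergeometric tables
    at least as extreme (probability no larger than the observed table's).
    """
    k, m, r, u = n_regulated_in_set, set_size, n_regulated_total, universe_size
    if m > u:
        raise ValueError("set size exceeds the universe")
    if not (0 <= k <= min(m, r)) or r > u:
        raise ValueError("counts do not form a valid 2x2 table")
    table = [[k, r - k], [m - k, u - r - (m - k)]]
    if min(table[0][1], table[1][1]) < 0:
        raise ValueError("counts do not form a valid 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classify_direction(n_up: int, n_down: int,
                       threshold: float = 0.6) -> str:
    """up / down when that direction holds >= 60% of regulated genes, else mixed."""
    total = n_up + n_down
    if total < 1:
        raise ValueError("no regulated genes to classify")
    if n_up / total >= threshold:
        return "up"
    if n_down / total >= threshold:
        return "down"
    return "mixed"


def summarize_sets(regulated_genes: pd.DataFrame, catalog: GeneSetCatalog,
                   universe: set, config: GeneSetConfig | None = None):
    """Category analysis over a catalog of gene sets.

    ``regulated_genes`` is the frame from :func:`apply_gene_filters`;
    ``universe`` is the set of genes represented by at least one
    non-promiscuous probe on the platform. A set is retained when its
    Fisher two-tail p is at or below the cutoff, at least
    ``min_regulated`` of its platform members are regulated, and those
    cover at least ``min_pct_regulated`` percent of the platform members.
    The set's BMC is the median over its regulated genes' BMCs.
    """
    cfg = config or GeneSetConfig()
    reg = set(regulated_genes["gene"]) & universe
    bmc = dict(zip(regulated_genes["gene"], regulated_genes["bmd"]))
    direction = dict(zip(regulated_genes["gene"], regulated_genes["direction"]))
    results = []
    for set_id in catalog:
        members = catalog.members(set_id) & universe
        if not members:
            continue
        hits = sorted(members & reg)
        if not hits:
            continue
        p = fisher_enrichment(len(hits), len(members), len(reg), len(universe))
        pct = 100.0 * len(hits) / len(members)
        if p > cfg.fisher_cutoff or len(hits) < cfg.min_regulated \
                or pct < cfg.min_pct_regulated:
            continue
        n_up = sum(direction[g] == "up" for g in hits)
        n_down = len(hits) - n_up
        results.append(GeneSetResult(
            set_id=set_id, set_name=catalog.name(set_id),
            n_members_on_platform=len(members), n_regulated=len(hits),
            fisher_p_two_tail=p, pct_regulated=pct,
            median_bmc=float(np.median([bmc[g] for g in hits])),
            n_up=n_up, n_down=n_down,
            direction_class=classify_direction(n_up, n_down,
                                               cfg.direction_threshold)))
    results.sort(key=lambda r: (r.fisher_p_two_tail, r.set_id))
    return results


def run_gene_set_analysis(probe_table: pd.DataFrame, annotation: ProbeAnnotation,
                          catalog: GeneSetCatalog, max_dose: float,
                          filter_config: FilterConfig | None = None,
                          set_config: GeneSetConfig | None = None,
                          platform_probes=None):
    """Filters + category tests in one call.

    The enrichment universe is every gene carried by at least one
    non-promiscuous probe among ``platform_probes`` (default: all
    annotated probes, i.e. the whole platform, not only probes that
    reached a BMC). Returns ``(results, regulated_genes, report)``.
    """
    genes, report = apply_gene_filters(probe_table, annotation, max_dose,
                                       filter_config)
    universe = annotation.platform_genes(platform_probes)
    results = summarize_sets(genes, catalog, universe, set_config)
    return results, genes, report
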
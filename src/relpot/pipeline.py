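"""Endpoint-level RPF orchestration: viability ceiling, per-readout joint
fits, and rank-correlation of potency orderings across readouts.

Each readout (a triglyceride assay, one qPCR gene, ...) is analysed
independently with the parallel-curve engine on raw, non-normalised
responses — per-experiment background differences are absorbed by the
covariate on the background parameter, so no pre-normalisation is needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import DoseResponseTable
from .exponential import ParallelCurveSpec, RPFResult, select_c_mode

__all__ = [
    "determine_max_concentration",
    "run_endpoint_rpf",
    "RpfPanel",
    "compare_rpf_rankings",
]


def determine_max_concentration(viability: pd.DataFrame,
                                threshold: float = 0.75) -> dict[str, float]:
    """Highest tested concentration keeping mean viability above threshold.

    ``viability`` has columns substance, concentration (uM) and viability
    (% of solvent control). The rule is pointwise: the highest tested
    concentration whose own mean viability is >= 100*threshold percent is
    selected, regardless of lower concentrations (cytotoxicity need not be
    monotone in practice). A substance whose every tested concentration
    falls below the threshold raises, advising a lower concentration
    range.
    """
    out: dict[str, float] = {}
    for substance, sub in viability.groupby("substance"):
        means = sub.groupby("concentration")["viability"].mean()
        ok = means[means >= 100.0 * threshold]
        ok = ok[ok.index > 0]
        if ok.empty:
            raise ValueError(
                f"{substance}: all tested concentrations drop viability below "
                f"{100 * threshold:.0f}% of control; re-range the assay lower")
        out[str(substance)] = float(ok.index.max())
    return out


def run_endpoint_rpf(data, index: str, level: float = 0.90,
                     seed: int | None = 0, **spec_kw) -> list[RPFResult]:
    """Joint parallel-curve RPF analysis for one readout.

    Builds the covariate scheme (background per substance x experiment,
    potency and variance per substance, shared shape), fits with both a
    free and a fixed-large plateau keeping the lower-AIC fit, and returns
    one :class:`RPFResult` per substance — never silently dropping one:
    substances without a clear trend come back ``undetermined``.
    """
    if isinstance(data, pd.DataFrame):
        data = DoseResponseTable(data)
    spec = ParallelCurveSpec(index_substance=index, level=level, seed=seed,
                             **spec_kw)
    fit = select_c_mode(data, spec)
    return fit.compute_rpfs(level)


class RpfPanel:
    """RPF results per readout, aligned across substances."""

    def __init__(self, results: dict[str, list[RPFResult]]):
        for readout, rs in results.items():
            if not any(r.rpf == 1.0 and r.status == "determined" for r in rs):
                raise ValueError(f"readout {readout!r} lacks an index substance")
        self.results = results

    @classmethod
    def from_tables(cls, tables: dict[str, DoseResponseTable], index: str,
                    level: float = 0.90, seed: int | None = 0) -> "RpfPanel":
        return cls({name: run_endpoint_rpf(tbl, index, level, seed)
                    for name, tbl in tables.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for readout, rs in self.results.items():
            for r in rs:
                rows.append(dict(readout=readout, **r.as_dict()))
        return pd.DataFrame(rows)

    def rpf_matrix(self) -> pd.DataFrame:
        """Substances x readouts matrix of point RPFs (NaN if undetermined)."""
        frame = self.to_frame()
        return frame.pivot(index="substance", columns="readout", values="rpf")


def compare_rpf_rankings(panel: RpfPanel,
                         external: pd.DataFrame | None = None,
                         min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlation of log-RPF rankings across readouts.

    ``external`` optionally adds published RPF columns (one column per
    published readout, indexed by substance). Correlations use pairwise-
    complete observations on log RPFs; undetermined RPFs are missing.
    Cells with fewer than ``min_shared`` shared substances are NaN. The
    matrix is symmetric with a unit diagonal.
    """
    mat = panel.rpf_matrix()
    if external is not None:
        mat = mat.join(external, how="outer")
    logmat = np.log(mat.where(mat > 0))
    cols = list(logmat.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            pair = logmat[[ci, cj]].dropna()
            if len(pair) < min_shared:
                rho = np.nan
            else:
                rho = stats.spearmanr(pair[ci], pair[cj]).statistic
            out.loc[ci, cj] = out.loc[cj, ci] = rho
    return out
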
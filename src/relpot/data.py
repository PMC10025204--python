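"""In-memory containers for the concentration-response pipeline.

Four artifacts flow through the pipeline: a probes x samples log2
expression matrix with one exposure concentration per sample, long-format
endpoint tables (substance / experiment / concentration / raw response),
probe-to-gene annotation, and a gene-set catalog. Each container
validates its own invariants at construction so downstream code can
assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "DoseResponseTable",
    "ProbeAnnotation",
    "GeneSetCatalog",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violates a container invariant."""


@dataclass
class ExpressionDataset:
    """Log2 expression values, probes x samples, one concentration per sample.

    Parameters
    ----------
    probe_ids : list of str
        Unique probe identifiers, one per row of ``values``.
    sample_labels : list of str
        One label per column.
    concentrations : ndarray
        Non-negative exposure concentration (uM) per sample; at least one
        sample must be an untreated control (concentration exactly 0).
    values : ndarray
        Matrix of already-normalised log2 intensities, shape
        ``(len(probe_ids), len(sample_labels))``; all finite.
    """

    probe_ids: list[str]
    sample_labels: list[str]
    concentrations: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n_probes, n_samples = len(self.probe_ids), len(self.sample_labels)
        if self.values.shape != (n_probes, n_samples):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n_probes} probes x {n_samples} samples"
            )
        if self.concentrations.shape != (n_samples,):
            raise ValidationError("one concentration per sample is required")
        if len(set(self.probe_ids)) != n_probes:
            dupes = pd.Series(self.probe_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate probe ids: {dupes}")
        if not np.all(np.isfinite(self.concentrations)) or np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be finite and non-negative")
        if not np.any(self.concentrations == 0):
            raise ValidationError("at least one control sample (concentration 0) is required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def concentration_groups(self) -> dict[float, np.ndarray]:
        """Column indices per distinct concentration (exact numeric equality)."""
        groups: dict[float, list[int]] = {}
        for j, conc in enumerate(self.concentrations):
            groups.setdefault(float(conc), []).append(j)
        return {c: np.asarray(idx) for c, idx in sorted(groups.items())}

    def probe_values(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_labels)


@dataclass
class DoseResponseTable:
    """Long-format endpoint records for one readout.

    ``frame`` has columns substance, experiment, concentration (uM, >= 0)
    and response (raw scale, strictly positive — the error model is
    lognormal, so a zero response has no likelihood).
    """

    frame: pd.DataFrame

    REQUIRED = ("substance", "experiment", "concentration", "response")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        f = self.frame
        conc = pd.to_numeric(f["concentration"], errors="coerce")
        resp = pd.to_numeric(f["response"], errors="coerce")
        if conc.isna().any() or (conc < 0).any():
            raise ValidationError("concentrations must be numeric and non-negative")
        if resp.isna().any() or (resp <= 0).any():
            raise ValidationError(
                "responses must be numeric and strictly positive (lognormal error model)"
            )
        f = f.copy()
        f["substance"] = f["substance"].astype(str)
        f["experiment"] = f["experiment"].astype(str)
        f["concentration"] = conc.astype(float).values
        f["response"] = resp.astype(float).values
        self.frame = f.reset_index(drop=True)
        for s, sub in f.groupby("substance"):
            if sub["concentration"].nunique() < 2:
                raise ValidationError(f"substance {s!r} needs >=2 distinct concentrations")
            if not (sub["concentration"] == 0).any():
                raise ValidationError(f"substance {s!r} has no control (concentration 0)")

    @property
    def substances(self) -> list[str]:
        return sorted(self.frame["substance"].unique())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ProbeAnnotation:
    """Probe -> gene mapping; probes hitting more than one gene are promiscuous."""

    mapping: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {str(p): {str(g) for g in gs} for p, gs in self.mapping.items()}
        empty = [p for p, gs in self.mapping.items() if not gs]
        if empty:
            raise ValidationError(f"probes with no gene assignment: {sorted(empty)}")

    def genes(self, probe_id: str) -> set[str]:
        return self.mapping.get(probe_id, set())

    def is_promiscuous(self, probe_id: str) -> bool:
        return len(self.mapping.get(probe_id, ())) > 1

    def platform_genes(self, probe_ids=None) -> set[str]:
        """Genes represented by >=1 non-promiscuous probe (the enrichment universe)."""
        probes = self.mapping.keys() if probe_ids is None else probe_ids
        out: set[str] = set()
        for p in probes:
            gs = self.mapping.get(p, set())
            if len(gs) == 1:
                out |= gs
        return out


@dataclass
class GeneSetCatalog:
    """Named gene sets sharing the annotation's gene namespace."""

    sets: dict[str, tuple[str, frozenset]] = field(default_factory=dict)
    """set_id -> (set_name, member gene ids)."""

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset]] = {}
        for set_id, (name, members) in self.sets.items():
            members = frozenset(str(g) for g in members)
            if not members:
                raise ValidationError(f"gene set {set_id!r} has no members")
            clean[str(set_id)] = (str(name), members)
        self.sets = clean

    def members(self, set_id: str) -> frozenset:
        return self.sets[set_id][1]

    def name(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)
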
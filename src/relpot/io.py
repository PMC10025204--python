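"""Readers and writers for the pipeline's tab-delimited on-disk formats.

Expression matrix layout (one file per readout):

    <field>      <sample 1>  <sample 2> ...   first row: sample labels
    <field>      <conc 1>    <conc 2>   ...   second row: concentration (uM)
    <probe id>   <value>     <value>    ...   one row per probe

The first cell of the two header rows is a field name (written as
``Sample`` / ``Concentration``; any text is accepted on read).

Endpoint tables are long-format TSV with a header row naming
``substance``, ``experiment``, ``concentration`` and ``response``.

Probe annotation is one ``probe_id<TAB>gene_id`` pair per line (a probe
mapping to several genes occupies several lines). Gene-set catalogs use a
GMT-like dialect: ``set_id<TAB>set_name<TAB>gene<TAB>gene...``.

All parsers are locale-independent (decimal point only) and raise
:class:`~relpot.io.ParseError` naming the offending 1-based line number.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    DoseResponseTable,
    ExpressionDataset,
    GeneSetCatalog,
    ProbeAnnotation,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_dose_response_table",
    "write_dose_response_table",
    "read_probe_map",
    "write_probe_map",
    "read_gene_sets",
    "write_gene_sets",
    "read_viability_table",
    "write_run_manifest",
]


class ParseError(ValueError):
    """Malformed input file; the message carries the 1-based line number."""


def _as_lines(source):
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return fh.read().splitlines()
    return source.read().splitlines()


def _open_out(target):
    if isinstance(target, (str, Path)):
        return open(target, "wt", encoding="utf-8"), True
    return target, False


def _float(token: str, line_no: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {line_no}: non-numeric {what}: {token!r}") from None


def read_expression_matrix(source) -> ExpressionDataset:
    """Parse the two-header-row expression matrix layout."""
    lines = [ln for ln in _as_lines(source) if ln.strip()]
    if len(lines) < 3:
        raise ParseError("line 1: expected label row, concentration row and >=1 probe row")
    labels = lines[0].split("\t")[1:]
    n = len(labels)
    if n == 0:
        raise ParseError("line 1: no sample labels found")
    conc_tokens = lines[1].split("\t")[1:]
    if len(conc_tokens) != n:
        raise ParseError(f"line 2: expected {n} concentrations, found {len(conc_tokens)}")
    concentrations = [_float(t, 2, "concentration") for t in conc_tokens]
    probe_ids: list[str] = []
    seen: set[str] = set()
    rows = np.empty((len(lines) - 2, n))
    for i, ln in enumerate(lines[2:], start=3):
        fields = ln.split("\t")
        if len(fields) != n + 1:
            raise ParseError(f"line {i}: expected {n + 1} fields, found {len(fields)}")
        pid = fields[0]
        if pid in seen:
            raise ParseError(f"line {i}: duplicate probe id {pid!r}")
        seen.add(pid)
        probe_ids.append(pid)
        rows[i - 3] = [_float(t, i, "expression value") for t in fields[1:]]
    return ExpressionDataset(probe_ids, labels, np.asarray(concentrations), rows)


def write_expression_matrix(dataset: ExpressionDataset, target) -> None:
    fh, close = _open_out(target)
    try:
        fh.write("Sample\t" + "\t".join(dataset.sample_labels) + "\n")
        fh.write("Concentration\t"
                 + "\t".join(repr(float(c)) for c in dataset.concentrations) + "\n")
        for pid, row in zip(dataset.probe_ids, dataset.values):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    finally:
        if close:
            fh.close()


def read_dose_response_table(source) -> DoseResponseTable:
    """Parse a long-format endpoint table (header + one record per line)."""
    if isinstance(source, (str, Path)):
        frame = pd.read_csv(source, sep="\t")
    else:
        frame = pd.read_csv(source, sep="\t")
    frame.columns = [c.strip().lower() for c in frame.columns]
    try:
        return DoseResponseTable(frame)
    except ValidationError as err:
        raise ValidationError(f"invalid dose-response table: {err}") from err


def write_dose_response_table(table: DoseResponseTable, target) -> None:
    table.frame.to_csv(target, sep="\t", index=False)


def read_probe_map(source) -> ProbeAnnotation:
    """One probe_id<TAB>gene_id pair per line; repeated probes accumulate genes."""
    mapping: dict[str, set[str]] = {}
    for i, ln in enumerate(_as_lines(source), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"line {i}: expected 'probe<TAB>gene', got {ln!r}")
        mapping.setdefault(fields[0], set()).add(fields[1])
    return ProbeAnnotation(mapping)


def write_probe_map(annotation: ProbeAnnotation, target) -> None:
    fh, close = _open_out(target)
    try:
        for probe in sorted(annotation.mapping):
            for gene in sorted(annotation.mapping[probe]):
                fh.write(f"{probe}\t{gene}\n")
    finally:
        if close:
            fh.close()


def read_gene_sets(source, annotation: ProbeAnnotation | None = None) -> GeneSetCatalog:
    """GMT-like catalog: set_id, set_name, then member genes, tab-separated.

    If an annotation is supplied, sets whose members are entirely absent
    from the platform raise a warning (likely namespace mismatch), not an
    error.
    """
    sets: dict[str, tuple[str, frozenset]] = {}
    for i, ln in enumerate(_as_lines(source), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {i}: expected set_id, set_name and >=1 gene")
        set_id, name = fields[0], fields[1]
        if set_id in sets:
            raise ParseError(f"line {i}: duplicate set id {set_id!r}")
        members = frozenset(g for g in fields[2:] if g)
        if not members:
            raise ParseError(f"line {i}: gene set {set_id!r} has no members")
        sets[set_id] = (name, members)
    catalog = GeneSetCatalog(sets)
    if annotation is not None:
        platform = set()
        for gs in annotation.mapping.values():
            platform |= gs
        for set_id in catalog:
            if not (catalog.members(set_id) & platform):
                warnings.warn(
                    f"gene set {set_id!r} shares no genes with the platform "
                    "annotation; check identifier namespaces",
                    stacklevel=2,
                )
    return catalog


def write_gene_sets(catalog: GeneSetCatalog, target) -> None:
    fh, close = _open_out(target)
    try:
        for set_id in sorted(catalog.sets):
            name, members = catalog.sets[set_id]
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")
    finally:
        if close:
            fh.close()


def read_viability_table(source) -> pd.DataFrame:
    """TSV with columns substance, concentration, viability (% of control)."""
    frame = pd.read_csv(source, sep="\t")
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"substance", "concentration", "viability"}
    if not required <= set(frame.columns):
        raise ParseError(f"viability table needs columns {sorted(required)}")
    if (frame["viability"] < 0).any() or (frame["concentration"] < 0).any():
        raise ValidationError("viability and concentration must be non-negative")
    return frame


def write_run_manifest(target, *, inputs: dict, config: dict, seed: int | None) -> None:
    """JSON manifest recording inputs, configuration and the RNG seed."""
    import hashlib

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
    }
    fh, close = _open_out(target)
    try:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    finally:
        if close:
            fh.close()
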
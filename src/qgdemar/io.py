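"""Reading and writing the pipeline's text formats.

Canonical interchange is tab-delimited text: an expression matrix with a
``probe_id`` first column, an optional ``gene`` second column, and one
column of log2 intensities per sample; plus a sample-metadata table
(sample, strain, phase, replicate).  A read-only adapter for GEO
series-matrix files is included for locally stored downloads — strain
and phase metadata must always be supplied externally, since GEO sample
titles are free text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deconvolution import DEFAULT_FDR_TARGET, DEFAULT_WINDOW, DetectionResult
from .design import DiscriminationVariable, ProbeMatrix

logger = logging.getLogger("qgdemar")


class MatrixFormatError(ValueError):
    """Malformed expression-matrix or series-matrix file."""


def _load_metadata(metadata) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        meta = metadata.copy()
    else:
        meta = pd.read_csv(metadata, sep="\t")
    if "sample" in meta.columns:
        meta = meta.set_index("sample")
    for col in ("strain", "phase"):
        if col not in meta.columns:
            raise MatrixFormatError(f"sample metadata lacks required column {col!r}")
    return meta


def read_matrix(path, metadata) -> ProbeMatrix:
    """Read a tab-delimited log2 expression matrix.

    First column ``probe_id``, optional second column ``gene``, remaining
    columns samples named in ``metadata`` (a DataFrame or path to a TSV
    with columns sample/strain/phase/replicate).  Duplicate probe ids,
    samples without metadata, and non-numeric cells raise errors; the
    parse error names the offending line.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "probe_id":
        raise MatrixFormatError(f"first column must be 'probe_id', got {raw.columns[0]!r}")
    raw = raw.set_index("probe_id")
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate probe ids: {dupes[:5]}")
    genes = None
    if len(raw.columns) and raw.columns[0] == "gene":
        genes = raw["gene"].replace("", pd.NA)
        raw = raw.drop(columns="gene")
    values = raw.apply(pd.to_numeric, errors="coerce")
    raw_missing = raw.isna() | raw.isin(["", "nan", "NaN", "NA"])
    bad = values.isna() & ~raw_missing
    if bad.to_numpy().any():
        row_pos = int(np.flatnonzero(bad.any(axis=1).to_numpy())[0])
        # +2: one for the header line, one for 1-based numbering
        raise MatrixFormatError(
            f"non-numeric cell in row for probe {values.index[row_pos]!r} (line {row_pos + 2})"
        )
    meta = _load_metadata(metadata)
    orphans = [c for c in values.columns if c not in meta.index]
    if orphans:
        raise MatrixFormatError(f"samples without metadata: {orphans}")
    return ProbeMatrix(values=values.astype(float), samples=meta, genes=genes)


def write_matrix(matrix: ProbeMatrix, path, metadata_path=None) -> None:
    """Write a ProbeMatrix (and optionally its sample metadata) as TSV."""
    out = matrix.values.copy()
    out.insert(0, "gene", matrix.genes)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="")
    if metadata_path is not None:
        meta = matrix.samples.copy()
        meta.index.name = "sample"
        meta.to_csv(metadata_path, sep="\t")


def read_geo_series_matrix(path, metadata=None, log2_transform: bool = False) -> ProbeMatrix:
    """Read a GEO series-matrix text file (optional adapter; local files only).

    Parses the expression block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``.  Values are taken as stored; pass
    ``log2_transform=True`` for linear-scale deposits (no auto-detection).
    Strain/phase metadata must be supplied externally; without it a
    minimal single-condition metadata table is synthesized so the matrix
    can at least be inspected.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise MatrixFormatError("no series_matrix_table block found") from None
    block = "\n".join(lines[start + 1 : end])
    if not block.strip():
        raise MatrixFormatError("empty expression block")
    table = pd.read_csv(StringIO(block), sep="\t")
    table.columns = [str(c).strip('"') for c in table.columns]
    table = table.set_index(table.columns[0])
    table.index = [str(i).strip('"') for i in table.index]
    table.index.name = "probe_id"
    values = table.apply(pd.to_numeric, errors="coerce").astype(float)
    if log2_transform:
        values = np.log2(values.where(values > 0))
    if metadata is not None:
        meta = _load_metadata(metadata)
    else:
        meta = pd.DataFrame(
            {"strain": "unknown", "phase": "unknown", "replicate": range(1, len(values.columns) + 1)},
            index=pd.Index(values.columns, name="sample"),
        )
        logger.warning("no sample metadata supplied for %s; using placeholders", path)
    return ProbeMatrix(values=values, samples=meta, genes=None)


def write_variable(variable: DiscriminationVariable, path) -> None:
    """Serialize one discrimination variable as TSV."""
    genes = variable.genes if variable.genes is not None else pd.Series(pd.NA, index=variable.values.index)
    out = pd.DataFrame(
        {
            "probe_id": variable.values.index,
            "gene": genes.reindex(variable.values.index).to_numpy(),
            "kind": variable.kind,
            "value": variable.values.to_numpy(),
            "definition": variable.definition,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_detection(result: DetectionResult, path, genes: pd.Series | None = None) -> None:
    """Serialize detections as TSV: probe, gene, variable, tail, threshold, FDR%."""
    rows = []
    for tail_name in ("upper", "lower"):
        tail = result.tail(tail_name)
        for probe in sorted(tail.probes, key=str):
            rows.append(
                {
                    "probe_id": probe,
                    "gene": (genes.get(probe) if genes is not None else None),
                    "variable_id": result.variable_id,
                    "tail": tail_name,
                    "threshold": tail.threshold,
                    "fdr_percent": tail.fdr_percent,
                }
            )
    pd.DataFrame(
        rows, columns=["probe_id", "gene", "variable_id", "tail", "threshold", "fdr_percent"]
    ).to_csv(path, sep="\t", index=False)


def detection_summary(result: DetectionResult) -> dict:
    """Machine-readable summary of one detection run."""
    out = {
        "variable_id": result.variable_id,
        "n_total": result.n_total,
        "null": {
            "mu_hat": result.null.mu_hat,
            "sigma_hat": result.null.sigma_hat,
            "window": list(result.null.window),
            "n_points_fit": result.null.n_points_fit,
            "fit_r2": result.null.fit_r2,
        },
    }
    for tail_name in ("upper", "lower"):
        tail = result.tail(tail_name)
        out[tail_name] = {
            "status": tail.status,
            "threshold": tail.threshold,
            "n_detected": tail.n_detected,
            "fdr_percent": tail.fdr_percent,
        }
    return out


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    matrix_path: str
    metadata_path: str
    q_lo: float = DEFAULT_WINDOW[0]
    q_hi: float = DEFAULT_WINDOW[1]
    fdr_target: float = DEFAULT_FDR_TARGET
    seed: int = 0
    output_dir: str = "."
    correction_mode: str = "cross"  # "cross" | "operon"
    operon_blacklist_path: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.q_lo < self.q_hi < 1:
            raise ValueError(f"require 0 < q_lo < q_hi < 1, got ({self.q_lo}, {self.q_hi})")
        if not 0 < self.fdr_target <= 100:
            raise ValueError(f"fdr_target must be in (0, 100], got {self.fdr_target}")
        if self.correction_mode not in ("cross", "operon"):
            raise ValueError(f"unknown correction_mode {self.correction_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(extra=extra, **kwargs)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
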
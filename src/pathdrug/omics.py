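"""Omics matrices (cell lines × genes) and their delimited-text I/O.

Three kinds are supported:

``expression``
    log-scale expression values (e.g. log2(TPM+1)); any real values.
``mutation``
    damaging-mutation status codes per gene: 0 = no mutation, 1 = mutation
    at allele frequency below 0.95, 2 = mutation at frequency ≥ 0.95.
``cnv_ratio``
    per-gene copy-number ratios (linear scale, ≥ 0); requires per-cell-line
    ploidy so ratios can be converted to absolute copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

OMICS_KINDS = ("expression", "mutation", "cnv_ratio")


@dataclass
class OmicsMatrix:
    """One omics layer: values for cell lines (rows) × genes (columns)."""

    kind: str
    cell_lines: list[str]
    genes: list[str]
    values: np.ndarray
    ploidy: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in OMICS_KINDS:
            raise ValueError(f"unknown omics kind {self.kind!r}; expected one of {OMICS_KINDS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_lines), len(self.genes)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_lines)} cell lines × {len(self.genes)} genes"
            )
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValueError("duplicate cell-line identifiers")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if self.kind == "mutation":
            if not np.isin(self.values, (0.0, 1.0, 2.0)).all():
                raise ValueError("mutation values must be in {0, 1, 2}")
        if self.kind == "cnv_ratio":
            if np.nanmin(self.values) < 0:
                raise ValueError("cnv_ratio values must be >= 0")
            if self.ploidy is None:
                raise ValueError("cnv_ratio matrix requires per-cell-line ploidy")
            missing = [c for c in self.cell_lines if c not in self.ploidy]
            if missing:
                raise ValueError(f"missing ploidy for cell line(s): {missing[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_lines, columns=self.genes)

    def row(self, cell_line: str) -> np.ndarray:
        return self.values[self.cell_lines.index(cell_line)]


def read_omics_csv(
    path: str | Path,
    kind: str,
    ploidy_path: str | Path | None = None,
    cnv_input: str = "linear",
    sep: str = ",",
) -> OmicsMatrix:
    """Read an omics matrix from delimited text.

    First column holds cell-line identifiers, the header row gene
    identifiers. For ``kind='cnv_ratio'`` a two-column ploidy table
    (cell_line, ploidy) is required, and ``cnv_input='log2p1'`` inverts a
    log2(x+1) transform on the stored ratios (v -> 2**v - 1) before use.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    if kind == "cnv_ratio" and cnv_input == "log2p1":
        values = np.exp2(values) - 1.0
    elif kind == "cnv_ratio" and cnv_input != "linear":
        raise ValueError(f"cnv_input must be 'linear' or 'log2p1', got {cnv_input!r}")
    ploidy = None
    if ploidy_path is not None:
        ploidy = read_ploidy(ploidy_path, sep=sep)
    return OmicsMatrix(
        kind=kind,
        cell_lines=[str(c) for c in df.index],
        genes=[str(g) for g in df.columns],
        values=values,
        ploidy=ploidy,
    )


def write_omics_csv(matrix: OmicsMatrix, path: str | Path, sep: str = ",") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="cell_line")


def read_ploidy(path: str | Path, sep: str = ",") -> dict[str, float]:
    """Read a two-column (cell_line, ploidy) table."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("ploidy table needs two columns: cell_line, ploidy")
    out = {str(k): float(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
    if any(v <= 0 for v in out.values()):
        raise ValueError("ploidy must be positive")
    return out


def write_ploidy(ploidy: dict[str, float], path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        {"cell_line": list(ploidy), "ploidy": list(ploidy.values())}
    ).to_csv(path, sep=sep, index=False)
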
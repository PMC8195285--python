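"""Core data containers and plain-text I/O.

The central object is :class:`GeneCountMatrix`: integer read counts with
genes as rows and samples as columns, paired with a per-sample design table
(diet group and time point). Counts are stored as a pandas DataFrame so the
rest of the pipeline can rely on label alignment rather than positional
bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["GeneCountMatrix", "cpm", "read_counts_tsv", "write_counts_tsv",
           "read_counts_mtx", "write_counts_mtx"]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, computed per sample (column)."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise InvalidArgumentError(f"samples with zero library size: {bad}")
    return counts.div(lib, axis=1) * 1e6


@dataclass
class GeneCountMatrix:
    """Gene-level read counts (genes x samples) with the sample design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene symbol, one column per sample. Values
        must be non-negative; they are raw (not depth-normalized) counts.
    design
        DataFrame indexed by sample name with at least the columns
        ``group`` (diet group, e.g. RFD/HFD) and ``time`` (time point).
    """

    counts: pd.DataFrame
    design: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.design is None:
            self.design = pd.DataFrame(index=self.counts.columns)
        if (np.asarray(self.counts.values) < 0).any():
            raise InvalidArgumentError("counts must be non-negative")
        if not self.counts.columns.equals(self.design.index):
            if set(self.counts.columns) != set(self.design.index):
                raise InvalidArgumentError(
                    "design index does not match count matrix columns"
                )
            self.design = self.design.loc[self.counts.columns]
        if self.counts.index.name is None:
            self.counts.index.name = "gene"

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def cpm(self) -> pd.DataFrame:
        return cpm(self.counts)

    def subset_genes(self, genes) -> "GeneCountMatrix":
        return GeneCountMatrix(self.counts.loc[genes].copy(), self.design.copy())

    def subset_samples(self, samples) -> "GeneCountMatrix":
        return GeneCountMatrix(
            self.counts[list(samples)].copy(), self.design.loc[list(samples)].copy()
        )


def read_counts_tsv(counts_path, design_path=None) -> GeneCountMatrix:
    """Read a counts TSV (first column gene symbol, remaining columns samples)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene"
    design = None
    if design_path is not None:
        design = pd.read_csv(design_path, sep="\t", index_col=0)
    return GeneCountMatrix(counts, design)


def write_counts_tsv(matrix: GeneCountMatrix, counts_path, design_path=None) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    if design_path is not None:
        out = matrix.design.copy()
        out.index.name = "sample"
        out.to_csv(design_path, sep="\t")


def read_counts_mtx(mtx_path, genes_path, samples_path, design_path=None) -> GeneCountMatrix:
    """Read counts from MatrixMarket plus row (gene) / column (sample) index files."""
    from scipy.io import mmread

    raw = mmread(str(mtx_path))
    mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
    genes = pd.read_csv(genes_path, header=None)[0].tolist()
    samples = pd.read_csv(samples_path, header=None)[0].tolist()
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    design = pd.read_csv(design_path, sep="\t", index_col=0) if design_path else None
    return GeneCountMatrix(counts, design)


def write_counts_mtx(matrix: GeneCountMatrix, mtx_path, genes_path, samples_path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(mtx_path), csr_matrix(matrix.counts.values))
    Path(genes_path).write_text("\n".join(matrix.genes) + "\n")
    Path(samples_path).write_text("\n".join(matrix.samples) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
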
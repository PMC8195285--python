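"""Gene-matrix bookkeeping: unexpressed genes, duplicate symbols, low expression.

The canonical order is drop_unexpressed -> resolve_duplicate_symbols ->
low_expression_filter; :func:`apply_filters` runs all three and returns the
accounting report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .data import GeneCountMatrix
from .errors import InvalidArgumentError

__all__ = [
    "FilterReport",
    "drop_unexpressed",
    "resolve_duplicate_symbols",
    "low_expression_filter",
    "apply_filters",
]


@dataclass
class FilterReport:
    """Accounting of the gene-matrix cleanup; the identity
    n_retained = n_input - removed(unexpressed) - resolved(duplicates)
    - removed(low expression) holds exactly."""

    n_input_genes: int = 0
    n_unexpressed_removed: int = 0
    n_duplicates_resolved: int = 0
    n_low_expression_removed: int = 0
    n_retained: int = 0

    def validate(self) -> None:
        expected = (
            self.n_input_genes
            - self.n_unexpressed_removed
            - self.n_duplicates_resolved
            - self.n_low_expression_removed
        )
        if self.n_retained != expected or min(asdict(self).values()) < 0:
            raise InvalidArgumentError(f"inconsistent filter report: {asdict(self)}")

    def as_dict(self) -> dict:
        return asdict(self)

    def summary_line(self) -> str:
        return (
            f"{self.n_input_genes} genes in; {self.n_unexpressed_removed} unexpressed "
            f"removed; {self.n_duplicates_resolved} duplicate symbols resolved; "
            f"{self.n_low_expression_removed} low-expression removed; "
            f"{self.n_retained} retained"
        )


def drop_unexpressed(matrix: GeneCountMatrix) -> tuple[GeneCountMatrix, int]:
    """Remove genes with zero reads in every sample; order preserved."""
    keep = matrix.counts.sum(axis=1) > 0
    out = GeneCountMatrix(matrix.counts.loc[keep].copy(), matrix.design.copy())
    return out, int((~keep).sum())


def resolve_duplicate_symbols(matrix: GeneCountMatrix) -> tuple[GeneCountMatrix, int]:
    """Keep, per duplicated symbol, the row with the highest total read count.

    Ties are broken by first occurrence in input order. Gene order of the
    retained rows is preserved.
    """
    counts = matrix.counts
    if counts.index.is_unique:
        return GeneCountMatrix(counts.copy(), matrix.design.copy()), 0
    totals = counts.sum(axis=1).to_numpy()
    order = range(len(counts))
    best: dict = {}
    for pos, symbol in zip(order, counts.index):
        if symbol not in best or totals[pos] > totals[best[symbol]]:
            best[symbol] = pos  # strict >: first occurrence wins ties
    keep_pos = sorted(best.values())
    n_resolved = len(counts) - len(keep_pos)
    out = GeneCountMatrix(counts.iloc[keep_pos].copy(), matrix.design.copy())
    return out, n_resolved


def low_expression_filter(
    matrix: GeneCountMatrix,
    min_reads_exclusive: int = 5,
    min_samples: int = 6,
) -> tuple[GeneCountMatrix, int]:
    """Retain genes with more than ``min_reads_exclusive`` reads (strictly)
    in at least ``min_samples`` samples."""
    if matrix.n_samples < min_samples:
        raise InvalidArgumentError(
            f"matrix has {matrix.n_samples} samples; need >= {min_samples}"
        )
    keep = (matrix.counts > min_reads_exclusive).sum(axis=1) >= min_samples
    out = GeneCountMatrix(matrix.counts.loc[keep].copy(), matrix.design.copy())
    return out, int((~keep).sum())


def apply_filters(
    matrix: GeneCountMatrix,
    min_reads_exclusive: int = 5,
    min_samples: int = 6,
) -> tuple[GeneCountMatrix, FilterReport]:
    """Run the three cleanup steps in canonical order and account for them."""
    report = FilterReport(n_input_genes=matrix.n_genes)
    matrix, report.n_unexpressed_removed = drop_unexpressed(matrix)
    matrix, report.n_duplicates_resolved = resolve_duplicate_symbols(matrix)
    matrix, report.n_low_expression_removed = low_expression_filter(
        matrix, min_reads_exclusive, min_samples
    )
    report.n_retained = matrix.n_genes
    report.validate()
    return matrix, report
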
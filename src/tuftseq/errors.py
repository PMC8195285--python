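"""Exception hierarchy for the tuftseq pipeline."""


class TuftseqError(Exception):
    """Base class for all tuftseq-specific errors."""


class InvalidArgumentError(TuftseqError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(TuftseqError):
    """Too few observations to compute the requested quantity."""


class InsufficientMarkersError(TuftseqError):
    """A cell type has too few marker genes present in the bulk matrix."""

    def __init__(self, cell_type: str, n_found: int, n_required: int):
        self.cell_type = cell_type
        self.n_found = n_found
        self.n_required = n_required
        super().__init__(
            f"cell type {cell_type!r} has {n_found} marker genes in the bulk "
            f"matrix; at least {n_required} are required for deconvolution"
        )


class InsufficientPermutationsError(TuftseqError):
    """Fewer distinct group-label permutations exist than required."""


class GMTParseError(TuftseqError):
    """A gene-set (GMT) file line could not be parsed."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"GMT parse error at line {line_number}: {message}")
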
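"""Exception types shared across the package."""


class TaxodelimError(Exception):
    """Base class for all package errors."""


class FormatError(TaxodelimError, ValueError):
    """An on-disk file violates its declared format."""


class InvariantError(TaxodelimError, ValueError):
    """An in-memory object violates a structural invariant."""


class AlignmentError(TaxodelimError, ValueError):
    """Pairwise alignment cannot be computed or interpreted."""


class SimulationError(TaxodelimError, ValueError):
    """Synthetic-data parameters are invalid or infeasible."""


class DelineationError(TaxodelimError, ValueError):
    """Rank delineation preconditions are violated."""
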
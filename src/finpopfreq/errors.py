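"""Exception types shared across the package."""


class FinPopFreqError(Exception):
    """Base class for all package-specific errors."""


class FeasibilityError(FinPopFreqError, ValueError):
    """A parameter combination violates the finite-population lattice or
    homozygosity bounds (e.g. 2*M*p not an integer, or P outside
    [max(0, 2p-1), p])."""


class ImpossibleObservationError(FinPopFreqError, ValueError):
    """The observed copy count has zero probability under every candidate
    population, signalling corrupt input (no confidence set exists at any
    significance level)."""


class TableFormatError(FinPopFreqError, ValueError):
    """A frequency table is structurally invalid (missing columns,
    non-numeric cells, unknown dialect)."""


class TableSumError(FinPopFreqError, ValueError):
    """Frequencies or copy counts in a table do not add up as required."""
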
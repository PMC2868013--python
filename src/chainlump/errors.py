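"""Exception hierarchy for chainlump.

All chainlump-specific failures derive from :class:`ChainlumpError` so callers
can catch the package's errors with a single ``except`` clause.  A few
exceptions are *signals* rather than failures (notably
:class:`NoValidClustering`) and are documented as such where they are raised.
"""


class ChainlumpError(Exception):
    """Base class for all chainlump errors."""


# ---------------------------------------------------------------------------
# Matrix validation


class NonSquare(ChainlumpError):
    """Input matrix is not square or labels do not match its dimension."""


class NegativeEntry(ChainlumpError):
    """A transition probability is negative beyond tolerance."""


class RowSumViolation(ChainlumpError):
    """A row of a transition matrix does not sum to one within tolerance."""

    def __init__(self, label, row_sum, tol):
        self.label = label
        self.row_sum = row_sum
        super().__init__(
            f"row {label!r} sums to {row_sum!r}, outside tolerance {tol!r} of 1"
        )


class InvalidPartition(ChainlumpError):
    """Blocks are empty, overlap, or do not cover the state labels."""


# ---------------------------------------------------------------------------
# Markov algebra


class NonUniqueStationary(ChainlumpError):
    """The eigenspace of eigenvalue 1 has dimension > 1 (several recurrent
    classes); no unique stationary distribution exists."""


class EmptyRestriction(ChainlumpError):
    """Restriction to an empty (or unknown) label set was requested."""


class ZeroRow(ChainlumpError):
    """After restriction a kept state has no remaining probability mass."""


class ZeroMassBlock(ChainlumpError):
    """A partition block carries zero stationary probability."""


# ---------------------------------------------------------------------------
# Information measure


class NotNormalized(ChainlumpError):
    """A probability table does not sum to one within tolerance."""


# ---------------------------------------------------------------------------
# Spectral machinery


class EigendecompositionFailure(ChainlumpError):
    """The eigendecomposition could not be computed reliably."""


class NoValidClustering(ChainlumpError):
    """The selected eigenvectors do not resolve into as many clusters as
    eigenvectors selected.  This is a signal, not a failure: it simply means
    the chosen eigenvectors do not define an aggregation at the given cut."""


class SearchBudgetExceeded(ChainlumpError):
    """The spectral subset search exhausted its node budget."""


# ---------------------------------------------------------------------------
# Codon domain


class UnknownCodonLabel(ChainlumpError):
    """A matrix label is not a codon of the genetic code in use."""


class InvalidGeneticCode(ChainlumpError):
    """A genetic-code table is malformed (wrong key set, no stop codons...)."""


# ---------------------------------------------------------------------------
# Synthetic generation


class InvalidProbability(ChainlumpError):
    """A probability parameter lies outside its admissible range."""


class InvalidSizes(ChainlumpError):
    """Planted block sizes are empty or non-positive."""
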
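"""Exception hierarchy shared across the package."""


class PhyloTraitsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhyloTraitsError):
    """An input table is missing required columns or has a malformed header."""


class ValidationError(PhyloTraitsError):
    """An input table violates a value-level invariant (e.g. non-positive trait)."""


class DesignError(PhyloTraitsError):
    """The data do not support the requested analysis design."""


class DegenerateTreeError(PhyloTraitsError):
    """The phylogeny cannot yield a valid correlation matrix (e.g. zero depth)."""


class FitError(PhyloTraitsError):
    """Model fitting failed to converge from every starting point."""


class NumericalError(PhyloTraitsError):
    """A numerical operation (factorization, eigendecomposition) failed."""
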
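"""Exception hierarchy shared across the package."""


class RopboError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RopboError):
    """A required column or field is missing or malformed."""


class ValidationError(RopboError):
    """A value violates a documented invariant (range, sign, finiteness)."""


class FamilyMismatchError(RopboError):
    """A fragment of the wrong family was supplied to an operation."""


class UnknownSyntheticCostError(RopboError):
    """A fragment has no synthesis-step count, so ligand cost is undefined."""


class EmptyFeasibleSetError(RopboError):
    """Every candidate was removed by the synthetic-scale feasibility filter."""


class EncodingMismatchError(RopboError):
    """Descriptor vectors with different encodings cannot be combined."""


class CollinearityError(RopboError):
    """A linear design matrix is rank deficient."""
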
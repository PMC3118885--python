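"""Exception hierarchy.

All package errors derive from :class:`EcosensError` so callers can catch a
single base class at pipeline boundaries.
"""


class EcosensError(Exception):
    """Base class for all ecosens errors."""


class SchemaError(EcosensError):
    """A grading scheme or weight configuration failed validation."""


class GradingError(EcosensError):
    """A raw value could not be graded (unknown category, out-of-domain)."""


class ContractError(EcosensError):
    """Inputs violate an operation's contract (shape, ids, normalization)."""


class NormalizationError(EcosensError):
    """A column cannot be normalized (zero maximum, non-positive cost value)."""


class DegenerateWeightsError(EcosensError):
    """No indicator discriminates between objects; entropy weights undefined."""


class SynthesisError(EcosensError):
    """Composite-index aggregation failed (missing leaf grades)."""


class CRSError(EcosensError):
    """A geometric operation requires a planar CRS with linear units."""
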
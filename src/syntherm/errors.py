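"""Exception hierarchy.

``ValidationError`` covers malformed inputs (bad units, unbalanced reactions,
schema violations); ``ComputationError`` covers states at which a quantity is
undefined (zero activities, non-positive rates, insufficient data). The CLI
maps them to exit codes 2 and 3 respectively.
"""


class SynthermError(Exception):
    """Base class for all package errors."""


class ValidationError(SynthermError):
    """Input fails a structural or schema check."""


class ComputationError(SynthermError):
    """Quantity is undefined or not computable at the given state."""


class SpeciesLookupError(ValidationError, KeyError):
    """A reaction references a species absent from the thermodynamic table."""


class ReactionBalanceError(ValidationError):
    """A reaction violates element or charge balance."""


class ActivityError(ComputationError):
    """A participating species has zero or missing activity."""


class InsufficientDataError(ComputationError):
    """Too few usable points for the requested estimate."""
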
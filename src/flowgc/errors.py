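"""Exception hierarchy for pipeline validation and numerical failures."""


class FlowgcError(Exception):
    """Base class for all package errors."""


class ValidationError(FlowgcError):
    """Input violates a documented contract (NaNs, duplicate ids, bad labels)."""


class DimensionError(FlowgcError):
    """Shape or node-count mismatch between inputs."""


class ParseError(FlowgcError):
    """A delimited file could not be read as a rectangular numeric matrix."""


class DegenerateInputError(FlowgcError):
    """A regression design is singular (constant or collinear series)."""


class InsufficientDataError(FlowgcError):
    """Too few usable samples to fit the requested model order."""
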
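"""Exception hierarchy shared across the toolkit."""


class CrosscellError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CrosscellError):
    """An on-disk file does not conform to its declared format."""


class SchemaError(CrosscellError):
    """A table is missing required columns or carries malformed values."""


class ParameterError(CrosscellError):
    """A user-supplied parameter is outside its valid domain."""


class ContractError(CrosscellError):
    """An operation's precondition was violated by its inputs."""
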
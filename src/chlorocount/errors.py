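"""Exception hierarchy shared across the pipeline."""


class ChlorocountError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ChlorocountError, ValueError):
    """A value violates a documented precondition or range."""


class ParseError(ChlorocountError, ValueError):
    """A text input (detection file, manifest, config) could not be parsed."""


class FormatError(ChlorocountError, ValueError):
    """A file is structurally wrong (dtype, channels, dimensionality)."""
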
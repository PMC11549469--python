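"""Exception hierarchy shared across the package."""


class BraincogError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BraincogError):
    """Invalid simulation or pipeline configuration."""


class FormatError(BraincogError):
    """Malformed tabular input (duplicate ids, bad cells, bad labels)."""


class AlignmentError(BraincogError):
    """Subject ids do not line up across tables."""
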
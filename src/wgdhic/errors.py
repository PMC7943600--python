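"""Exception hierarchy for the wgdhic pipeline."""


class WgdHicError(Exception):
    """Base class for all wgdhic errors."""


class ConfigurationError(WgdHicError):
    """A parameter or configuration value is invalid."""


class DataError(WgdHicError):
    """Input data violates a contract of the operation."""


class DegenerateMatrixError(DataError):
    """A contact matrix has no usable bins left."""
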
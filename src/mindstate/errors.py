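"""Exception types shared across the pipeline."""


class MindstateError(Exception):
    """Base class for all package errors."""


class ParameterError(MindstateError, ValueError):
    """A numeric parameter is outside its valid range."""


class ConfigurationError(MindstateError, ValueError):
    """A configuration is structurally invalid (missing stage, impossible layout)."""


class FormatError(MindstateError, ValueError):
    """An unsupported or malformed file format was requested."""


class DataError(MindstateError, ValueError):
    """Input data violate a precondition (too short, missing states, mismatched ids)."""
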
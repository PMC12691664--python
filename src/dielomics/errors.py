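"""Exception hierarchy shared across the package."""


class DielomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(DielomicsError):
    """Invalid simulation or pipeline configuration."""


class InputError(DielomicsError):
    """Malformed or inconsistent user input (files, counts, sequences)."""


class ParseError(InputError):
    """A file could not be parsed; message carries location when known."""


class DesignError(DielomicsError):
    """Sample metadata incompatible with the requested analysis design."""


class NormalizationError(DielomicsError):
    """Normalization impossible (e.g. an all-zero sample)."""


class SelectionError(DielomicsError):
    """A selection procedure (soft threshold, eigengene) degenerated."""
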
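"""Shared exception types."""


class PhasePaintError(Exception):
    """Base class for all package errors."""


class DimensionError(PhasePaintError):
    """Array shapes or sizes are inconsistent."""


class FormatError(PhasePaintError):
    """Unsupported or malformed file format."""


class ConfigurationError(PhasePaintError):
    """Invalid parameter or configuration value."""


class GenerationError(PhasePaintError):
    """Synthetic scene could not be generated (e.g. infeasible packing)."""


class DataError(PhasePaintError):
    """Invalid or empty dataset."""


class TrainingError(PhasePaintError):
    """Optimization failed (e.g. divergent loss)."""
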
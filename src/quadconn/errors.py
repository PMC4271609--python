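"""Exception types shared across the pipeline."""


class QuadconnError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(QuadconnError, ValueError):
    """Invalid configuration value caught before any compute runs."""


class PlacementError(QuadconnError, RuntimeError):
    """Phantom geometry could not be realized (grid too small, etc.)."""


class EpochingError(QuadconnError, ValueError):
    """A stimulus-locked epoch would fall outside the recording."""


class DataUnusableError(QuadconnError, RuntimeError):
    """Quality control removed so much data that nothing remains."""


class FormatError(QuadconnError, ValueError):
    """A file on disk does not parse as the expected format."""
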
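"""Exception types shared across the package."""


class TpearError(Exception):
    """Base class for all package errors."""


class FormatError(TpearError):
    """A file does not conform to the expected layout (bad header, wrong columns)."""


class DataError(TpearError):
    """The data content violates a contract (non-monotonic index, flat signal for alignment)."""


class ConfigError(TpearError):
    """Inconsistent or out-of-range configuration values."""


class SignalTooShortError(TpearError):
    """Signal shorter than the embedding window, even after the short-trial fallback."""


class FlatSignalError(TpearError):
    """No oscillatory component present; gait-event detection is undefined."""
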
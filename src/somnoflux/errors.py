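"""Exception types used across the package."""


class SomnofluxError(Exception):
    """Base class for package errors."""


class ConfigurationError(SomnofluxError):
    """Invalid simulation or run configuration."""


class InputError(SomnofluxError):
    """Malformed or inconsistent input data."""


class CalibrationFailure(SomnofluxError):
    """Sensor calibration did not meet acceptance rules."""
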
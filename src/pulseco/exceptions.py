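"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes, so stages can fail loudly
without losing information about *what kind* of failure occurred.
"""


class PulsecoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PulsecoError, ValueError):
    """Invalid run or sampling configuration."""


class DomainError(PulsecoError, ValueError):
    """Input outside the physical/mathematical domain of an operation."""


class ConvergenceError(PulsecoError, RuntimeError):
    """An iterative solver failed to reach its convergence criterion."""


class CalibrationError(PulsecoError, RuntimeError):
    """The generator produced too many implausible subjects."""


class TrainingError(PulsecoError, RuntimeError):
    """Model training diverged (non-finite loss)."""


class DegenerateWaveformError(DomainError):
    """A waveform with zero amplitude range cannot be normalized."""
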
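"""Exception hierarchy.

All pacelock-specific failures derive from :class:`PacelockError` so callers
can catch the package's errors without masking programming mistakes.
"""


class PacelockError(Exception):
    """Base class for all pacelock errors."""


class InvalidIPRCError(PacelockError, ValueError):
    """The phase-response curve is empty, non-finite, or degenerate."""


class NoSpikeError(PacelockError, RuntimeError):
    """Phase integration failed to reach threshold within the time budget."""


class InputError(PacelockError, ValueError):
    """Malformed input data (non-finite currents, bad spike tables, ...)."""


class SingularDesignError(PacelockError, ValueError):
    """The charge-matrix regression design is rank deficient."""


class UndefinedStatisticError(PacelockError, ValueError):
    """A statistic is undefined for this input (empty sample, VS = 0, ...)."""


class DegenerateMapError(PacelockError, ValueError):
    """Return map has non-isolated fixed points (e.g. rigid rotation by 1)."""


class NoLockingError(PacelockError, ValueError):
    """No locking-phase prediction: the relevant Fourier mode vanishes."""


class TuningError(PacelockError, RuntimeError):
    """A bisection calibration (noise SD, beta, bias current) failed."""


class ConfigurationError(PacelockError, ValueError):
    """Inconsistent or incomplete simulation configuration."""
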
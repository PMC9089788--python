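"""Exception hierarchy.

Every user-facing failure mode maps onto one of these; internal logic
errors raise plain ``AssertionError``/``RuntimeError``.
"""


class AtriakitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AtriakitError, ValueError):
    """A preset or analysis configuration violates its invariants."""


class FormatError(AtriakitError, ValueError):
    """An on-disk artifact is malformed; the message names the offending key."""


class InsufficientBeatsError(AtriakitError, RuntimeError):
    """Fewer complete paced beats than the ensemble average requires."""


class InsufficientSinusBeatsError(AtriakitError, RuntimeError):
    """No qualifying run of consecutive regular sinus beats for signal averaging."""


class NoSignalError(AtriakitError, RuntimeError):
    """No pixels survive amplitude-based ROI pruning (or an empty ROI was given)."""
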
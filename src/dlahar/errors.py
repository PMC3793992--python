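"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`HarError` so callers can trap
pipeline failures without catching unrelated exceptions.
"""


class HarError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(HarError, ValueError):
    """An argument is outside its documented domain."""


class FormatError(HarError, ValueError):
    """A file does not match the expected on-disk layout."""


class IntegrityError(HarError, ValueError):
    """Data shapes or lengths are mutually inconsistent."""


class DetectionError(HarError, RuntimeError):
    """The synchronization event could not be found in the signal."""


class TrainingError(HarError, RuntimeError):
    """A classifier (sub)system cannot be trained on the given data."""


class GenerationError(HarError, RuntimeError):
    """The simulator produced a signal violating a sensor invariant."""
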
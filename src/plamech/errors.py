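"""Exception hierarchy.

All package errors derive from :class:`PlamechError` so callers can catch
everything with one handler; the subclasses distinguish bad parameters,
degenerate inputs (e.g. constant images fed to an auto-threshold), file-format
problems, and the various ways a force-curve analysis can fail.
"""


class PlamechError(Exception):
    """Base class for all errors raised by plamech."""


class InvalidParameterError(PlamechError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(PlamechError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. constant image)."""


class FormatError(PlamechError, ValueError):
    """A file or table does not match the expected on-disk format."""


class CalibrationError(PlamechError, RuntimeError):
    """Deflection-sensitivity calibration failed (no contact region found)."""


class NoContactError(PlamechError, RuntimeError):
    """No probe-sample contact detectable in a force curve."""


class FitError(PlamechError, RuntimeError):
    """An elasticity fit produced a non-physical result (e.g. non-positive slope)."""


class InsufficientDataError(PlamechError, RuntimeError):
    """Too few samples in the fitting range."""


class GeneratorError(PlamechError, RuntimeError):
    """A synthetic-data specification cannot be realised."""
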
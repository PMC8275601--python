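"""Exception hierarchy.

Everything raised on purpose derives from :class:`UsblurError` so callers
(and the CLI) can distinguish degenerate/invalid input from genuine bugs.
"""


class UsblurError(Exception):
    """Base class for all errors raised by usblur."""


class ParameterError(UsblurError, ValueError):
    """Invalid blur parameters (e.g. non-positive length)."""


class SizeError(UsblurError, ValueError):
    """A kernel does not fit in the target image/frame."""


class DegenerateImageError(UsblurError, ValueError):
    """Image carries no usable signal (all-zero, constant, ...)."""


class OutOfBranchError(UsblurError, ValueError):
    """A spectral ratio falls outside the principal sinc branch."""


class InconsistentMomentsError(UsblurError, ValueError):
    """Moment differences have the wrong sign for any motion blur."""


class NoBlurDetectedError(UsblurError, RuntimeError):
    """No dominant motion-blur signature found in the input."""


class LengthIndeterminateError(UsblurError, RuntimeError):
    """Too few spectral zero lines to measure the blur length."""
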
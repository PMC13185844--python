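"""Exception hierarchy shared by all dipchar modules.

Every error raised by the library derives from :class:`DipcharError`, so CLI
entry points can map any library failure onto a categorized non-zero exit.
"""


class DipcharError(Exception):
    """Base class for all dipchar errors."""


class InsufficientDataError(DipcharError):
    """Too few samples/points to perform the requested fit or estimate."""


class DegenerateFitError(DipcharError):
    """The design matrix of a regression is singular (e.g. all x identical)."""


class DomainError(DipcharError):
    """An argument lies outside its physically meaningful domain."""


class DoubleCorrectionError(DipcharError):
    """Hydrostatic subtraction requested on an already-corrected trace."""


class NoContactError(DipcharError):
    """Contact-detection threshold never met anywhere in the trace."""


class NoGradientError(DipcharError):
    """No admissible evaluation pair for a finite-difference gradient."""


class EmptyFeasibleSetError(DipcharError):
    """A fidelity map contains no resolvable grayscale entries."""


class NoScorableLayersError(DipcharError):
    """Lag alignment leaves no frame/truth pair to score."""


class StackError(DipcharError):
    """Image-stack manifest inconsistency (gaps, mixed shapes, bad depth)."""


class ConfigError(DipcharError):
    """Run-configuration file is malformed or contains unknown keys."""
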
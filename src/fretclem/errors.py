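"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: 0 success, 2 usage error,
3 data error, 4 convergence error.
"""


class FretClemError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 3


class InvalidParameterError(FretClemError, ValueError):
    """A physical parameter is outside its valid domain."""

    exit_code = 2


class InsufficientPhotonsError(FretClemError):
    """Too few photons for the requested estimator (fall back to the
    center-of-mass mean lifetime where applicable)."""

    exit_code = 3


class ConvergenceError(FretClemError):
    """Optimizer failed to converge; the best candidate found is attached.

    Attributes
    ----------
    best_candidate : object or None
        The best (parameters, diagnostics) pair found across starts.
    """

    exit_code = 4

    def __init__(self, message, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate


class DegenerateFiducialsError(FretClemError):
    """Fewer than three fiducial pairs, or all pairs collinear."""

    exit_code = 3


class MissingPairError(FretClemError):
    """A construct lacks one of its paired (control, quencher) measurements."""

    exit_code = 3


class ParseError(FretClemError):
    """An interchange file is malformed; message names file, line and field."""

    exit_code = 3
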
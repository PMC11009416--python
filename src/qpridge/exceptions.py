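"""Exception hierarchy shared across the package."""


class QPRidgeError(Exception):
    """Base class for all qpridge errors."""


class ValidationError(QPRidgeError, ValueError):
    """Invalid input data or configuration (CLI exit code 2)."""


class ConvergenceError(QPRidgeError, RuntimeError):
    """Iterative fitting failed to converge (CLI exit code 3).

    Carries the last iterate so callers can inspect where the
    algorithm stalled.
    """

    def __init__(self, message, last_beta=None, n_iter=None):
        super().__init__(message)
        self.last_beta = last_beta
        self.n_iter = n_iter


class RankDeficiencyError(QPRidgeError, ValueError):
    """The weighted cross-product matrix is singular."""
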
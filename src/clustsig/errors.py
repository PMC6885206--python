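"""Exception hierarchy."""


class ClustsigError(Exception):
    """Base class for package errors."""


class DegenerateDataError(ClustsigError):
    """Input data cannot support the requested model (e.g. zero variance)."""


class FitFailedError(ClustsigError):
    """EM failed after all restarts (component collapse / variance floor)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SeparationError(ClustsigError):
    """Monotone Cox partial likelihood: a coefficient diverges to +-inf."""

    def __init__(self, message, beta=None, loglik_path=None):
        super().__init__(message)
        self.beta = beta
        self.loglik_path = loglik_path


class CollinearityError(ClustsigError):
    """Design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = columns or []
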
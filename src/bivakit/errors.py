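"""Exception hierarchy shared across the package."""


class BivakitError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BivakitError, ValueError):
    """An input violates a mathematical or physiological precondition."""


class ConfigurationError(BivakitError, ValueError):
    """Invalid configuration: missing columns, bad mappings, mixed units."""


class EmptyInputError(BivakitError, ValueError):
    """An operation received no usable rows."""


class IncompleteRecordError(BivakitError, ValueError):
    """A subject record lacks fields required by the operation."""


class ExtrapolationError(BivakitError, ValueError):
    """A query age lies outside the support of a fitted reference."""


class DegenerateGeometryError(BivakitError, ValueError):
    """Singular covariance: no nondegenerate ellipse / T^2 exists."""


class CollinearityError(BivakitError, ValueError):
    """Rank-deficient design matrix; names the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class ConvergenceError(BivakitError, RuntimeError):
    """An iterative fit failed to converge; carries the optimiser trace."""

    def __init__(self, message, trace=None):
        self.trace = trace
        super().__init__(message)


class ParseError(BivakitError, ValueError):
    """A reference or cohort table is malformed; lists offending rows."""

    def __init__(self, message, rows=None):
        self.rows = rows or []
        super().__init__(message)


class PipelineError(BivakitError, RuntimeError):
    """A pipeline stage aborted; carries the stage name and partial report."""

    def __init__(self, stage, message, report=None):
        self.stage = stage
        self.report = report
        super().__init__(f"[{stage}] {message}")
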
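"""Exception hierarchy for panelscreen."""


class PanelscreenError(Exception):
    """Base class for all panelscreen errors."""


class InvalidDesignError(PanelscreenError):
    """Raised when a study design or simulation configuration is unusable."""


class DataError(PanelscreenError):
    """Raised on empty, inconsistent, or referentially broken input tables."""


class RankDeficiencyError(PanelscreenError):
    """Raised when the fixed-effect design is singular.

    Parameters
    ----------
    aliased : list of str
        Names of the design columns that are linearly dependent on earlier
        columns.
    """

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "fixed-effect design is rank deficient; aliased columns: "
            + ", ".join(self.aliased)
        )


class ConvergenceError(PanelscreenError):
    """Raised when the REML optimizer fails to converge; carries a trace."""

    def __init__(self, message, trace=None):
        self.trace = trace or []
        super().__init__(message)


class DegenerateFitError(PanelscreenError):
    """Raised when a fit is degenerate (e.g. zero residual variance)."""


class UsageError(PanelscreenError):
    """Raised on API misuse (non-nested models, unknown terms, bad types)."""
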
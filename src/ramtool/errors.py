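"""Exception hierarchy for ramtool.

All package-specific failures derive from :class:`RAMError` so callers can
catch one base class at tool boundaries (CLI, scripts).
"""


class RAMError(Exception):
    """Base class for all ramtool errors."""


class ModelStructureError(RAMError):
    """The in-memory model violates a structural invariant (dangling ids,
    duplicate ids, inconsistent flags)."""


class ClassificationError(ModelStructureError):
    """A reaction touches an inconsistent combination of species classes and
    cannot be assigned to exactly one reaction group."""


class ParameterizationError(RAMError):
    """A required numeric parameter is missing or invalid (e.g. a catalyzed
    reaction with a zero turnover number, a quota species without weight)."""


class DomainError(RAMError):
    """An argument is outside its mathematical domain (negative amounts,
    nonpositive rates or lengths)."""


class ParseError(RAMError):
    """Malformed sequence or table input."""


class MissingKcatError(ParameterizationError):
    """No usable turnover-rate observation remains after filtering."""


class SBMLValidationError(RAMError):
    """An SBML document violates the resource-allocation dialect rules.

    Carries the list of :class:`~ramtool.sbml_io.Finding` objects that were
    fatal, when produced by the validator.
    """

    def __init__(self, message, findings=()):
        super().__init__(message)
        self.findings = list(findings)


class SolverError(RAMError):
    """The LP backend failed or returned a non-optimal status."""


class InfeasibleProblemError(SolverError):
    """The discretized problem (or a balanced-growth feasibility test) has no
    feasible point, e.g. quota demands unsatisfiable from the initial state."""


class UnboundedProblemError(SolverError):
    """The LP is unbounded; usually a missing capacity constraint."""


class GrowthRateError(RAMError):
    """Experimental growth rate exceeds the model optimum: the turnover
    numbers should be checked before tuning maintenance."""
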
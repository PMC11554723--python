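"""Exception hierarchy for the corsinorm pipeline."""


class CorsinormError(Exception):
    """Base class for all package errors."""


# --- session scoring ---

class MalformedProtocolError(CorsinormError):
    """A span block violates the administration protocol (e.g. fewer than 3 targets)."""


class ProtocolOrderError(CorsinormError):
    """Responses recorded where the administration should already have stopped."""


class MalformedSessionError(CorsinormError):
    """A supraspan session violates its structural limits (e.g. more than 18 trials)."""


class InvalidResponseError(CorsinormError):
    """A tapping response contains an impossible cube identifier."""


# --- norming ---

class EmptyFamilyError(CorsinormError):
    """No transformation in the candidate family is admissible for the predictor."""


class DegenerateDesignError(CorsinormError):
    """Design matrix is rank deficient or a predictor is constant."""


class NoSignificantModelError(CorsinormError):
    """No candidate predictor subset reaches omnibus significance."""


class DivergenceError(CorsinormError):
    """Requested power not reachable within the search bound."""


# --- grids ---

class MissingCovariateError(CorsinormError):
    """A span-bearing correction equation was evaluated without a span."""


class DomainError(CorsinormError):
    """A covariate value lies outside the domain of its transformation."""


# --- cutpoints ---

class SampleTooSmallError(CorsinormError):
    """n too small for a distribution-free tolerance bound at the requested confidence."""


class DegenerateDistributionError(CorsinormError):
    """All adjusted scores identical; rank-based bands are undefined."""


# --- synthetic data ---

class InvalidSpecError(CorsinormError):
    """A cohort specification violates its invariants (e.g. non-PSD correlations)."""


class ConvergenceError(CorsinormError):
    """Iterative correlation matching failed within the iteration budget."""


# --- comparison ---

class EmptyComparisonError(CorsinormError):
    """No overlapping, non-excluded participants to compare."""


class UndefinedAUCError(CorsinormError):
    """AUC requested with only one class present in the truth labels."""


# --- io ---

class ValidationError(CorsinormError):
    """Tabular input failed validation; message lists the offending rows."""
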
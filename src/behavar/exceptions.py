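"""Exception hierarchy for behavar."""


class BehavarError(Exception):
    """Base class for all behavar errors."""


class ConfigurationError(BehavarError):
    """A configuration (column map, analysis config, CLI argument) is invalid."""


class ValidationError(BehavarError):
    """Input data violate a structural invariant of the trial table."""


class DegenerateDataError(BehavarError):
    """Data are structurally valid but carry no usable information
    (e.g. a constant trait column cannot be standardized)."""


class RankDeficiencyError(BehavarError):
    """The fixed-effect design matrix is rank deficient; carries the
    offending term name when it can be identified."""

    def __init__(self, message: str, term: str | None = None):
        super().__init__(message)
        self.term = term


class AlignmentError(BehavarError):
    """Posterior draw sets that must be iteration-aligned are not
    (different draw counts or different observation sets)."""


class SamplerError(BehavarError):
    """The MCMC run produced a non-finite log posterior; carries a
    diagnostic state dump."""

    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message)
        self.state = state or {}
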
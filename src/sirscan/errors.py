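"""Exception types shared across the pipeline stages."""


class SirscanError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SirscanError, ValueError):
    """An argument violates a documented precondition."""


class InvalidRecordError(SirscanError, ValueError):
    """A cohort or person-period record is malformed (e.g. nonpositive interval)."""


class NoEventsError(SirscanError, ValueError):
    """A model fit was requested on data with zero diagnosed cases."""


class SingularDesignError(SirscanError, ValueError):
    """The design matrix is rank deficient."""


class NoCasesError(SirscanError, ValueError):
    """A spatial test was requested with zero total observed cases."""


class SchemaError(SirscanError, KeyError):
    """Input table is missing a required column or covariate label."""


class MissingDataError(SirscanError, ValueError):
    """Required input values are absent (e.g. empty scenario-dose list)."""


class StageError(SirscanError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")
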
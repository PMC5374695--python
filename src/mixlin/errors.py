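"""Exception hierarchy for mixlin."""


class MixlinError(Exception):
    """Base class for all mixlin errors."""


class DesignError(MixlinError, ValueError):
    """Invalid mixture design: bad weights, unknown sample types, missing replicates."""


class FormatError(MixlinError, ValueError):
    """A table does not match the declared file dialect (e.g. a required column is missing)."""


class DataError(MixlinError, ValueError):
    """Structurally valid input whose content is unusable (duplicate IDs, all-zero samples, ...)."""


class CollinearityError(DataError):
    """Regression predictors are (numerically) collinear; the OLS problem is singular."""


class PipelineError(MixlinError):
    """Pipeline configuration or orchestration failure."""
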
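"""Exception hierarchy for the pipeline.

Every error raised by s1pop derives from :class:`PipelineError` so callers can
catch pipeline failures without masking programming errors.
"""


class PipelineError(Exception):
    """Base class for all s1pop errors."""


class ContractError(PipelineError, ValueError):
    """A function was called outside its documented contract."""


class BaselineDegenerateError(PipelineError):
    """The lowest-percentile baseline is not positive; dF/F0 is undefined."""


class UndefinedPreferenceError(PipelineError):
    """Preference index undefined because the cell's maximum amplitude is 0."""


class ProtocolError(PipelineError):
    """A stimulus protocol is inconsistent with itself or with a recording."""


class MissingTrialError(ProtocolError):
    """The (stimulus, trial) grid is incomplete.

    Attributes
    ----------
    missing : list of (stimulus_label, trial_index) pairs not found.
    """

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing (stimulus, trial) events: {self.missing}")


class DegenerateNullError(PipelineError):
    """The permutation null has zero spread; a z-score is undefined."""


class DegenerateProjectionError(PipelineError):
    """Input to the state-space projection carries no variance."""


class AssemblyError(PipelineError):
    """Pseudo-population assembly failed (e.g. mismatched trial counts)."""


class StratificationError(PipelineError):
    """Cross-validation folds cannot be stratified for the given labels."""


class LoadError(PipelineError):
    """A data file could not be parsed or failed validation on load."""


class ConfigError(PipelineError):
    """A run configuration value is invalid."""
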
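"""Exception types raised across the pipeline."""


class DielBFCError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(DielBFCError, ValueError):
    """A sample design request is malformed (e.g. empty time grid)."""


class InvalidSpecError(DielBFCError, ValueError):
    """A simulation request is internally inconsistent."""


class DegreesOfFreedomError(DielBFCError, ValueError):
    """The design cannot support the requested ANOVA (names the offending level)."""


class UndefinedEvidenceError(DielBFCError, ValueError):
    """Marginal likelihood requested for a cluster with no observed values."""


class NoMergeError(DielBFCError, ValueError):
    """A merge was requested on a partition with fewer than two clusters."""


class ConfigurationError(DielBFCError, ValueError):
    """A rhythm/model configuration is inconsistent (e.g. numerator harmonic missing)."""


class UndefinedPhaseError(DielBFCError, ValueError):
    """Phase requested for a cluster with no diurnal component."""


class PipelineError(DielBFCError, RuntimeError):
    """An end-to-end pipeline stage failed; message names the stage."""
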
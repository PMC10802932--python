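"""Exception hierarchy shared across the pipeline.

The CLI maps these onto its exit-code contract: validation problems exit 2,
stage failures inside a pipeline run exit 3.
"""


class TopPathwaysError(Exception):
    """Base class for all package errors."""


class ValidationError(TopPathwaysError):
    """Inputs violate a documented precondition or schema."""


class LoadError(TopPathwaysError):
    """A file could not be read or its parts disagree (names the offending file)."""


class EmptyDatasetError(TopPathwaysError):
    """An operation removed every cell (or was handed an empty dataset)."""


class StageError(TopPathwaysError):
    """A pipeline stage failed; carries the stage and transition names."""

    def __init__(self, stage: str, transition: str, cause: Exception):
        self.stage = stage
        self.transition = transition
        self.cause = cause
        super().__init__(
            f"stage '{stage}' failed for transition '{transition}': {cause}"
        )
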
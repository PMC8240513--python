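"""Exceptions shared across the package."""


class CanopyGCError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(CanopyGCError):
    """Trial design is internally inconsistent (e.g. more genotypes than plots)."""


class InvalidGeometryError(CanopyGCError):
    """Plot geometry cannot accommodate the requested sampling region."""


class MissingDataError(CanopyGCError):
    """An estimator was handed an empty sensor stream for a plot."""


class UnknownEventError(CanopyGCError):
    """A sampling event id is not part of the schedule."""


class IntegrityError(CanopyGCError):
    """Duplicate or conflicting rows in a ground-cover table."""


class StageError(CanopyGCError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
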
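"""Exception hierarchy for the mindcost pipeline."""


class MindcostError(Exception):
    """Base class for all package errors."""


class SchemaError(MindcostError):
    """A register table does not have the required structure (e.g. missing column)."""


class ValidationError(MindcostError):
    """A register table violates a row-level invariant.

    Carries the offending row indices (0-based positions within the table)
    so callers can point at the data that broke the rule.
    """

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class CatalogueError(MindcostError):
    """The disorder-definition catalogue is malformed."""


class ConfigError(MindcostError):
    """Study or pipeline configuration is invalid."""


class DeflatorError(MindcostError):
    """A money amount refers to a year outside the deflator series."""


class PipelineError(MindcostError):
    """A pipeline stage failed; message names the stage and the cause."""
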
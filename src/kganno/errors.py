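"""Exception hierarchy.

Every error raised by the library derives from :class:`KgannoError` so callers
can catch library failures without masking programming errors.
"""


class KgannoError(Exception):
    """Base class for all library errors."""


class OntologyParseError(KgannoError):
    """An OBO file could not be parsed."""


class GmtParseError(KgannoError):
    """A GMT gene-set file line is malformed."""


class IntegrityError(KgannoError):
    """A structural invariant of the knowledge graph is violated."""


class UnknownTermError(KgannoError, KeyError):
    """A node id / name / synonym could not be resolved in the graph."""


class AmbiguousTermError(KgannoError):
    """A name resolved to more than one graph node."""


class ConstantVectorError(KgannoError):
    """Correlation is undefined because one vector has zero variance."""


class ParameterError(KgannoError, ValueError):
    """A numeric parameter is outside its valid range."""


class ConfigurationError(KgannoError):
    """Run configuration is inconsistent with the supplied inputs."""


class RetrievalError(KgannoError):
    """No graph evidence could be retrieved for any candidate."""


class BackendError(KgannoError):
    """The annotation backend failed or returned an unusable response."""


class StageError(BackendError):
    """A pipeline stage failed for a specific cluster."""

    def __init__(self, stage: int, cluster_id, message: str):
        self.stage = stage
        self.cluster_id = cluster_id
        super().__init__(f"stage {stage} failed for cluster {cluster_id!r}: {message}")


class ContractViolationError(BackendError):
    """A backend decision fell outside the allowed candidate set."""
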
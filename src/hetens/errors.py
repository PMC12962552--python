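"""Exception hierarchy shared by all pipeline stages."""


class HetensError(Exception):
    """Base class for package-specific errors."""


class FormatError(HetensError):
    """A tabular input violates the expected dialect (missing column, bad value)."""


class ReferentialIntegrityError(HetensError):
    """An edge references a node id absent from the node table."""


class GraphLookupError(HetensError, KeyError):
    """A node id was not found in the graph."""

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0] if self.args else ""


class ConfigurationError(HetensError):
    """A parameter combination is invalid or infeasible."""


class ConsistencyError(HetensError):
    """Internal pipeline tables disagree; indicates a pipeline bug upstream."""
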
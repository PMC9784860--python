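"""Exception hierarchy.

The CLI maps these onto distinct exit codes: stream/file problems (2),
schema/config problems (3), computation problems (4).
"""


class EndoskillError(Exception):
    """Base class for all package errors."""


class StreamReadError(EndoskillError):
    """A video container or frame directory could not be opened or decoded."""


class EmptyStreamError(StreamReadError):
    """A source was readable but contained zero frames."""


class SchemaError(EndoskillError):
    """An annotation log, scene spec or config file failed validation."""


class ComputationError(EndoskillError):
    """A metric is undefined for the given input (e.g. no frame pairs)."""
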
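"""Error taxonomy shared across the package.

Three families map onto the CLI exit codes: configuration problems
(bad config files, unknown centers/categories, missing columns),
data problems (malformed or inconsistent input tables), and
computation problems (operations that are undefined for the given
inputs, e.g. allocating a pool over all-zero drivers).
"""


class CEAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CEAError):
    """Invalid configuration: unknown names, missing drivers, bad schemas."""


class DataError(CEAError):
    """Malformed or internally inconsistent input data."""


class ComputationError(CEAError):
    """A requested computation is undefined for the supplied inputs."""


class SchemaError(DataError):
    """A table is missing required columns or carries unexpected ones."""
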
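"""Exception hierarchy for fediv."""


class FedivError(Exception):
    """Base class for all fediv errors."""


class SchemaError(FedivError):
    """A trait schema is malformed or a required column is missing."""


class ValidationError(FedivError):
    """An input record violates the schema or table contract."""


class ConfigError(FedivError):
    """A run or generator configuration value is invalid."""


class DegenerateHullError(FedivError):
    """A point set is affinely dependent so its convex hull volume is undefined."""
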
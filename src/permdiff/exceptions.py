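"""Exception hierarchy shared across the pipeline."""


class PermdiffError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PermdiffError, ValueError):
    """An input table violates the expected schema."""


class ParseError(PermdiffError, ValueError):
    """A line of an input file could not be parsed."""


class ConfigError(PermdiffError, ValueError):
    """A configuration value or combination is invalid."""
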
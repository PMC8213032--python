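"""Exception types shared across the package."""


class SaltshiftError(Exception):
    """Base class for package errors."""


class InvalidConfigError(SaltshiftError, ValueError):
    """A configuration object violates its invariants."""


class SchemaError(SaltshiftError, ValueError):
    """An input table fails schema validation; message carries row diagnostics."""


class ConservationError(SaltshiftError, RuntimeError):
    """Persons were created or destroyed during a Markov cycle."""
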
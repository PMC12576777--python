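"""Exception hierarchy."""


class LattpartError(Exception):
    """Base class for all package-specific errors."""


class InputError(LattpartError):
    """Invalid user input (geometry, topology, arguments)."""


class ConfigurationError(LattpartError):
    """Invalid force-field / search configuration."""


class ParseError(LattpartError):
    """Malformed file; carries the offending path and line number."""

    def __init__(self, message: str, path: str = "", line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(loc + message)
        self.path = path
        self.line = line


class PartitionError(LattpartError):
    """A partition ledger violates one of its sign or additivity contracts."""


class BenchmarkError(LattpartError):
    """Missing or inconsistent data in a polymorph-pair benchmark."""
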
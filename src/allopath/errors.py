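"""Exception hierarchy shared across the package."""


class AllopathError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(AllopathError):
    """A PDB record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(AllopathError):
    """An input (file, selection, site) resolved to nothing."""


class SelectionError(AllopathError):
    """A selection expression is malformed or empty where atoms are required."""


class AtomMismatchError(AllopathError):
    """Two structures could not be paired atom-by-atom.

    ``report`` lists the unmatched identity keys on each side so the caller
    can see exactly what was missing rather than getting a silent
    intersection.
    """

    def __init__(self, message: str, only_in_a=(), only_in_b=()):
        self.only_in_a = list(only_in_a)
        self.only_in_b = list(only_in_b)
        detail = ""
        if self.only_in_a:
            detail += f"; only in first ({len(self.only_in_a)}): {self.only_in_a[:5]}"
        if self.only_in_b:
            detail += f"; only in second ({len(self.only_in_b)}): {self.only_in_b[:5]}"
        super().__init__(message + detail)


class DisconnectedNetworkError(AllopathError):
    """The elastic network is not connected at the chosen cutoff."""

    def __init__(self, components):
        self.components = components
        sizes = sorted((len(c) for c in components), reverse=True)
        super().__init__(
            f"elastic network has {len(components)} connected components "
            f"(sizes {sizes}); increase the cutoff"
        )


class ConfigError(AllopathError):
    """A run configuration is malformed (unknown key, bad type, bad value)."""
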
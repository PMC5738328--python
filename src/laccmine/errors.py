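"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class LaccmineError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LaccmineError):
    """Malformed biological input (bad characters, wrong lengths, ...)."""


class InputError(LaccmineError):
    """Missing or unreadable input file."""


class ConfigError(LaccmineError):
    """Invalid configuration (bad signature pattern, bad parameter)."""


class NumericalError(LaccmineError):
    """A numerical routine could not produce a well-defined answer."""


class ExtractionError(LaccmineError):
    """A required residue position lies outside the sequence."""
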
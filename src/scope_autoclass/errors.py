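"""Exception hierarchy shared across the package."""


class ScopeAutoclassError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ScopeAutoclassError):
    """A release file could not be parsed; carries file name and line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


class IntegrityError(ScopeAutoclassError):
    """Cross-file or cross-object consistency violation (dangling ids, bad tree)."""


class UnknownIdentifierError(ScopeAutoclassError, KeyError):
    """A sunid/sid lookup failed."""

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return Exception.__str__(self)
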
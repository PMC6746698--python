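"""Exception hierarchy shared across the package."""


class TilabError(Exception):
    """Base class for package errors."""


class ValidationError(TilabError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(TilabError, ValueError):
    """A file parses but violates the documented dialect (e.g. bad label code)."""


class ConvergenceError(TilabError, RuntimeError):
    """A numerical fit failed to converge; carries diagnostics in args."""
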
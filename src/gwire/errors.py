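"""Exception hierarchy.

Validation problems (bad user input, malformed files, out-of-domain
arguments) raise :class:`ValidationError`; failures of the numerics
themselves (no root in bracket, all fits diverged) raise
:class:`ComputationError`.  The CLI maps these to exit codes 2 and 3.
"""


class GwireError(Exception):
    """Base class for all package errors."""


class ValidationError(GwireError, ValueError):
    """Invalid input: domain violations, malformed files, bad configuration."""


class ComputationError(GwireError, RuntimeError):
    """A numerical procedure failed (non-convergence, no bracketed root, ...)."""
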
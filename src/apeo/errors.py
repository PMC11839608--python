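"""Exception hierarchy shared across the package."""


class ApeoError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ApeoError, ValueError):
    """A numeric input violates a mathematical precondition (e.g. tau <= 0)."""


class ShapeError(ApeoError, ValueError):
    """Array arguments have inconsistent shapes or lengths."""


class ConfigError(ApeoError, ValueError):
    """A configuration mapping is malformed; the message names the key."""


class ConstraintError(ApeoError, ValueError):
    """An activity parameter violates its box constraint; names the bound."""


class InfeasibleError(ApeoError, RuntimeError):
    """No feasible action remains after constraint masking."""
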
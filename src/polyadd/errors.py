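"""Exception hierarchy shared by all polyadd modules.

The CLI maps these onto distinct exit codes (usage=2, domain=3, numerical=4),
so library code should raise the most specific class that applies.
"""


class PolyaddError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PolyaddError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(PolyaddError, ValueError):
    """Required configuration (e.g. a monomer molar mass) is missing or conflicting."""


class NumericalError(PolyaddError, RuntimeError):
    """An iterative numerical procedure failed (integration, root finding)."""


class ConsistencyError(PolyaddError, ValueError):
    """Inputs violate a cross-quantity consistency requirement (e.g. mass mismatch)."""
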
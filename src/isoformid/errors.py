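"""Exception hierarchy shared across the package."""


class IsoformidError(Exception):
    """Base class for all package errors."""


class FormulaParseError(IsoformidError, ValueError):
    """Malformed or disallowed elemental formula text."""


class InfeasibleTransformationError(IsoformidError, ValueError):
    """Formula subtraction would produce a negative element count."""


class ConfigurationError(IsoformidError, ValueError):
    """Missing isotope data, bad tolerance, or invalid run configuration."""


class DomainError(IsoformidError, ValueError):
    """Operation called outside its mathematical domain."""
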
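"""Exception hierarchy shared across the toolkit."""


class LnaClampError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(LnaClampError, ValueError):
    """An input violates a documented invariant (bad residue, bad bounds, ...)."""


class FormatError(ValidationError):
    """A sequence file does not parse under the declared format."""


class EmptySelectionError(ValidationError):
    """A filter or group label matched no records."""


class DesignInfeasibleError(LnaClampError):
    """No candidate satisfies the design constraints (e.g. Tm window)."""


class InsufficientSpecificityError(DesignInfeasibleError):
    """Too few host-specific positions to place LNA bases on a clamp."""
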
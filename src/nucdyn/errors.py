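"""Exception types shared across the package."""


class NucdynError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NucdynError, ValueError):
    """Input violates a documented contract (ordering, bounds, overlap...)."""


class ParseError(NucdynError, ValueError):
    """Malformed input file; the message names the offending line."""
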
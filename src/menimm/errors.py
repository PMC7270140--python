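"""Exception hierarchy shared across the package."""


class MenimmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MenimmError):
    """Input failed a structural or domain check (bad file, bad label, bad shape)."""


class DegenerateInputError(MenimmError):
    """Numerically degenerate input: zero variance, constant matrix, empty group."""
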
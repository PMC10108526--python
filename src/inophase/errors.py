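"""Exception types shared across the toolkit."""


class InophaseError(Exception):
    """Base class for all toolkit errors."""


class FormatError(InophaseError, ValueError):
    """A file does not conform to the documented TSV dialect."""


class ValidationError(InophaseError, ValueError):
    """An in-memory object violates a domain invariant."""


class ConfigError(InophaseError, ValueError):
    """Invalid configuration or threshold combination."""


class LayoutError(InophaseError, ValueError):
    """Feature layout of inputs does not match the trained model."""


class SimulationSpecError(InophaseError, ValueError):
    """A simulation specification is internally inconsistent."""
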
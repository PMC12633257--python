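"""Exception hierarchy for deltacircuit."""


class DeltaCircuitError(Exception):
    """Base class for all package errors."""


class InvalidKineticsError(DeltaCircuitError):
    """Synapse or channel kinetic parameters are unusable (e.g. non-positive taus)."""


class InvalidStateError(DeltaCircuitError):
    """A gating state lies outside [0, 1]."""


class IntegrationError(DeltaCircuitError):
    """Numerical integration diverged; message names the offending input."""


class ValidationError(DeltaCircuitError):
    """A spec object failed structural validation."""


class MappingError(DeltaCircuitError):
    """A coefficient key does not resolve to any channel or synaptic target."""


class AlignmentError(DeltaCircuitError):
    """Two curves that must share a grid do not."""


class UndefinedRatioError(DeltaCircuitError):
    """A group-mean ratio has a zero denominator."""
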
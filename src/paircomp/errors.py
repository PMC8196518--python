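"""Exception hierarchy shared across the package."""


class PaircompError(Exception):
    """Base class for package errors."""


class ConfigurationError(PaircompError):
    """A configuration field is invalid; the message names the field."""


class SimulationError(PaircompError):
    """A simulation request cannot be satisfied (e.g. SV longer than a chromosome)."""


class EstimationError(PaircompError):
    """A statistical estimate cannot be formed from the given input."""


class ContractViolation(PaircompError):
    """An input object does not satisfy a documented precondition."""
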
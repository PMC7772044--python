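"""Exception hierarchy for masstex."""


class MassTexError(Exception):
    """Base class for all masstex errors."""


class ConfigurationError(MassTexError, ValueError):
    """A configuration object violates its contract (bad fractions, even support, ...)."""


class SizeError(MassTexError, ValueError):
    """An image or map is too small (or the wrong shape) for the requested operation."""


class AlignmentError(MassTexError, ValueError):
    """Feature blocks or label vectors that must align row-wise do not."""


class DegenerateLabelsError(MassTexError, ValueError):
    """A label vector with fewer than two classes where two are required."""


class ContractViolationError(MassTexError, RuntimeError):
    """A pluggable backend returned output violating its declared contract."""
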
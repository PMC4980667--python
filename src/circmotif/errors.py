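"""Package-wide exception types."""


class CircmotifError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CircmotifError, ValueError):
    """A configuration value is outside its documented domain."""


class PlacementError(CircmotifError):
    """Simulated genes cannot be placed without overlap."""


class TruthSpecError(CircmotifError, ValueError):
    """A requested true junction does not lie on annotated exon boundaries."""


class ChimericTableFormatError(CircmotifError, ValueError):
    """The chimeric TSV does not match the documented dialect."""


class LayoutError(CircmotifError, ValueError):
    """A SELEX library layout is internally inconsistent."""


class EmptySequenceError(CircmotifError, ValueError):
    """An input sequence is empty where a non-empty one is required."""


class GroupSizeError(CircmotifError, ValueError):
    """A comparison group is too small for the requested statistic."""


class EfficiencyFitError(CircmotifError, ValueError):
    """A primer-efficiency dilution series cannot be fit (non-negative slope)."""
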
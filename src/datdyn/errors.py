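"""Exception hierarchy shared across the package."""


class DatdynError(Exception):
    """Base class for all datdyn errors."""


class FormatError(DatdynError):
    """An input file does not follow the expected layout."""


class CorruptInterleaveError(FormatError):
    """Two-channel photometry rows are too unbalanced to demultiplex."""


class ValidationError(DatdynError):
    """An argument or configuration value violates a precondition."""


class UnitError(ValidationError):
    """Unit tags of two traces do not match at a stage boundary."""


class ResolutionError(ValidationError):
    """A requested kinetic timescale is unresolvable at the sampling rate."""


class DegenerateFitError(DatdynError):
    """A regression or control-channel fit is unusable (e.g. non-positive)."""


class FitError(DatdynError):
    """A nonlinear fit failed to converge from every start."""


class BelowDetectionError(DatdynError):
    """Evoked signal never exceeds the detection threshold; site excluded."""
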
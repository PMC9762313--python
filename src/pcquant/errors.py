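"""Exception hierarchy for the pipeline.

Every error raised by pcquant derives from :class:`PCQuantError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class PCQuantError(Exception):
    """Base class for all pcquant errors."""


class FormatError(PCQuantError):
    """A file could not be read as the expected format."""


class AxisAmbiguityError(PCQuantError):
    """Image axes could not be identified and no axis declaration was given."""


class CalibrationError(PCQuantError):
    """Missing or non-positive spatial/temporal calibration."""


class SchemaError(PCQuantError):
    """Records passed to a table writer do not share a schema."""


class FrameMismatchError(PCQuantError):
    """Two images/masks expected to share a frame of reference do not."""


class DegenerateHistogramError(PCQuantError):
    """Automatic thresholding attempted on a constant image."""


class DegenerateBaselineError(PCQuantError):
    """Relative growth requested with a zero-area first timepoint."""


class DegenerateSectionError(PCQuantError):
    """Section thickness is at least the extent of the sectioned solid."""


class PackingError(PCQuantError):
    """Requested scene geometry could not be placed without overlap."""


class ValidationError(PCQuantError):
    """A configuration value violates a parameter invariant."""
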
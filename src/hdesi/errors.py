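"""Exception hierarchy for the hdesi pipeline."""


class HdesiError(Exception):
    """Base class for all package errors."""


class ParameterError(HdesiError, ValueError):
    """An argument is outside its documented domain."""


class GeometryError(HdesiError, ValueError):
    """Invalid spatial configuration (source outside brain, bad fiducials, ...)."""


class CapacityError(HdesiError, ValueError):
    """Requested events do not fit into the recording."""


class InputError(HdesiError, ValueError):
    """Malformed or inconsistent input data."""


class FormatError(HdesiError, ValueError):
    """A file does not conform to its declared on-disk format."""


class UndefinedMetricError(HdesiError, ZeroDivisionError):
    """A metric's denominator is empty (no visual marks, no detections, ...)."""


class NumericError(HdesiError, ArithmeticError):
    """A linear system is singular beyond numerical tolerance."""


class NoPeakError(HdesiError, ValueError):
    """No usable peak / rising phase in a waveform."""
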
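"""Exception types shared across the package."""


class NircalError(Exception):
    """Base class for all package errors."""


class FormatError(NircalError):
    """A file violated the expected on-disk layout (ragged rows, duplicate
    IDs, non-numeric cells, non-monotonic wavelength axis, ...)."""


class DegenerateSpectrumError(NircalError):
    """A spectrum (or reference vector) is constant or otherwise unusable
    for the requested transform or metric."""


class InvalidMeasurementError(NircalError):
    """An assay measurement violates its physical preconditions."""


class IncompatibleAxisError(NircalError):
    """Prediction spectra are on a different wavelength axis than the model."""


class SelectionError(NircalError):
    """Wavelength selection produced an unusable (e.g. empty) variable set."""
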
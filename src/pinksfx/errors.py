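"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition."""


class UnsupportedSymmetryError(InvalidInputError):
    """Space group outside the supported presets (P41212, P1)."""


class GeometryInconsistencyError(ValueError):
    """A scattered-beam vector is not consistent with elastic scattering."""


class DegenerateProfileError(InvalidInputError):
    """A reciprocal point with zero effective radius cannot be integrated."""


class UndefinedMetricError(ValueError):
    """A merging statistic has no defined value on this dataset."""


class StreamParseError(ValueError):
    """A reflection-stream file is malformed; message names the line."""
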
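"""Exception hierarchy for the standing-gradient model package."""


class CsfSgError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CsfSgError, ValueError):
    """A physical parameter is outside its admissible range."""


class GeometryInfeasibleError(CsfSgError, ValueError):
    """Microvilli overlap: the packing density leaves no inter-microvillar space.

    Raised when sigma * pi * r_mv**2 >= 1 (equivalently p**2 <= pi * r_mv**2),
    so the hydraulic diameter of the functional unit would be non-positive.
    Monte-Carlo drivers catch this and reject (never clip) the sample.
    """


class SolverError(CsfSgError, RuntimeError):
    """The boundary-value solver failed to converge, even under continuation."""


class ConfigError(CsfSgError, ValueError):
    """A run configuration is malformed or missing required fields."""
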
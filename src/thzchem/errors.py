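"""Exception hierarchy shared across the pipeline stages."""


class ThzChemError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ThzChemError, ValueError):
    """A caller-supplied argument is out of the documented domain."""


class GridMismatchError(ThzChemError, ValueError):
    """Two objects that must share an axis (time or wavenumber) do not."""


class NumericDomainError(ThzChemError, ArithmeticError):
    """A computation left its numeric domain (e.g. log of a zero amplitude)."""


class EmptyBandError(ThzChemError, ValueError):
    """Band cropping retained no grid points."""


class DegenerateSpectrumError(ThzChemError, ValueError):
    """A spectrum has zero variance and cannot be SNV-normalized."""


class DegenerateFeatureError(ThzChemError, ValueError):
    """A constant feature column cannot be autoscaled."""


class InvalidStateError(ThzChemError, RuntimeError):
    """An operation was called before its prerequisite state exists."""
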
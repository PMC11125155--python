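"""Exception hierarchy.

Every named failure mode of the pipeline raises a distinct subclass of
:class:`PdfShellError` so callers can react per stage.
"""


class PdfShellError(Exception):
    """Base class for all package errors."""


class ProfileFormatError(PdfShellError):
    """A P(r) file could not be parsed in any supported dialect."""


class NonMonotoneGridError(PdfShellError):
    """Distance grid r is not strictly increasing."""


class TooFewPointsError(PdfShellError):
    """Profile has fewer than the minimum number of samples."""


class NonFiniteValueError(PdfShellError):
    """NaN or infinity encountered in profile data."""


class ScaleError(PdfShellError):
    """An absolute-scale quantity was requested from a relative-scale profile."""


class UnknownElementError(PdfShellError):
    """Chemical formula contains an unrecognised element symbol."""


class MonomerSpecError(PdfShellError):
    """Invalid monomer parameters (non-positive mass, cmc >= concentration, ...)."""


class NoExtremumError(PdfShellError):
    """Derivative has no interior maximum / required minima are missing."""


class TruncatedSupportError(PdfShellError):
    """P(r) never falls below the D_max detection threshold."""


class GeometryError(PdfShellError):
    """Inconsistent sizes (e.g. 2 R_sh >= D_max) or infeasible branch mapping."""


class DegenerateContrastError(PdfShellError):
    """Contrast configuration with (near-)zero net scattering weight."""


class NoSolutionError(PdfShellError):
    """Equation system has no admissible root / FOM grid entirely infeasible."""
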
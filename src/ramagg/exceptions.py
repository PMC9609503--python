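"""Exception hierarchy for the ramagg pipeline."""


class RamaggError(Exception):
    """Base class for all ramagg errors."""


class SpectrumParseError(RamaggError):
    """Raised when a spectrum file cannot be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line is not None else ""))


class InsufficientDataError(RamaggError):
    """Too few data points for the requested operation."""


class AxisOrderError(RamaggError):
    """Wavenumber axis is not strictly ascending."""


class DomainError(RamaggError):
    """A numeric argument is outside its valid domain."""


class ConfigError(RamaggError):
    """Run configuration is invalid or incomplete."""


class NormalizationError(RamaggError):
    """No usable reference band for intensity normalization."""


class DeconvolutionError(RamaggError):
    """A multi-peak fit failed; carries diagnostics when available."""

    def __init__(self, message: str, fit_result=None):
        self.fit_result = fit_result
        super().__init__(message)


class LookupError_(RamaggError):
    """A requested component/chain/atom does not exist."""


class UndefinedRatioError(RamaggError):
    """Denominator band has non-positive fitted height."""


class UndefinedFractionError(RamaggError):
    """All component areas are zero; fractions undefined."""


class UndefinedLagError(RamaggError):
    """Lag time requested from a non-converged sigmoid fit."""


class StructureParseError(RamaggError):
    """Malformed PDB records; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line is not None else ""))


class EmptyStructureError(RamaggError):
    """No ATOM records survived parsing/filtering."""


class CongruenceError(RamaggError):
    """Two structures do not share a congruent atom selection."""


class EmptyAssignmentError(RamaggError):
    """No residues with computable backbone dihedrals."""
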
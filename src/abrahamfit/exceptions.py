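"""Exception hierarchy.

All package-specific failures derive from :class:`AbrahamFitError` so callers
can catch one type at pipeline boundaries; subclasses carry the diagnostic
named in their message (offending solvent, element, unknown, ...).
"""


class AbrahamFitError(Exception):
    """Base class for all abrahamfit errors."""


class IncompleteDescriptorsError(AbrahamFitError):
    """A required solute descriptor is absent for the requested evaluation."""


class MalformedCoefficientsError(AbrahamFitError):
    """A process-coefficient record is internally inconsistent."""


class UnknownElementError(AbrahamFitError):
    """No McGowan atomic volume is available for an element."""


class EmptyMoleculeError(AbrahamFitError):
    """A molecular composition with no atoms was supplied."""


class UnitError(AbrahamFitError):
    """A measurement carries a unit the operation cannot handle."""


class SolventMetadataError(AbrahamFitError):
    """Density or molar mass needed for a unit conversion is missing."""


class TemperatureRangeError(AbrahamFitError):
    """A temperature outside the validity band of the correction."""


class MissingCoefficientsError(AbrahamFitError):
    """A measurement's solvent has no usable coefficient records."""


class UnderdeterminedError(AbrahamFitError):
    """Fewer constraints than free unknowns."""


class UnidentifiableError(AbrahamFitError):
    """The design matrix is rank deficient, or an unknown never appears."""
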
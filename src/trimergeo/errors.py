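"""Exception hierarchy.

All package errors derive from :class:`TrimerGeoError` so callers can catch
one base class; subclasses mirror the analysis stages.
"""


class TrimerGeoError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(TrimerGeoError):
    """A structure file could not be parsed."""


class SelectionError(TrimerGeoError):
    """A chain/residue selection could not be resolved."""


class ConfigurationError(TrimerGeoError):
    """Invalid user-supplied configuration or parameters."""


class CapabilityError(TrimerGeoError):
    """The input lacks data required for the requested operation
    (e.g. symmetry expansion without cell/operators)."""


class SpecError(TrimerGeoError):
    """An invalid synthetic-assembly specification."""


class GeometryError(TrimerGeoError):
    """Degenerate geometry (e.g. empty domain selection)."""


class ClassificationError(TrimerGeoError):
    """Chains do not form a single cyclic orbit."""


class ComparisonError(TrimerGeoError):
    """Distance-class summaries cannot be compared (label mismatch)."""


class SuperpositionError(TrimerGeoError):
    """Too few / degenerate point pairs for rigid superposition."""


class AlignmentError(TrimerGeoError):
    """Structure alignment failed or inputs too small."""


class InterfaceError(TrimerGeoError):
    """Contact/interface computation on empty or invalid parts."""


class ScanError(TrimerGeoError):
    """Cysteine-pair scan could not run (e.g. no CB atoms)."""


class ValidationError(TrimerGeoError):
    """Invalid value passed to a utility (sequence, mass, ...)."""
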
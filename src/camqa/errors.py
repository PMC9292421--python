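"""Exception hierarchy shared across the package."""


class CamqaError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CamqaError):
    """A structure file could not be parsed."""


class EmptyStructureError(CamqaError):
    """No atoms remain after filtering."""


class MissingRadiusError(CamqaError):
    """An atom has no radius and the table offers no default."""


class GeometryError(CamqaError):
    """Coordinates are non-finite or a construction is geometrically impossible."""


class NeedsMultimerError(CamqaError):
    """An operation requiring at least two chains received a monomer."""


class ConsistencyError(CamqaError):
    """Two objects that must describe the same structure do not."""


class UndefinedScoreError(CamqaError):
    """A score's denominator is zero (e.g. target without contacts)."""


class MappingError(CamqaError):
    """Model and target chain compositions cannot be matched."""


class CombinatorialLimitError(MappingError):
    """Too many interchangeable chains to enumerate permutations."""


class DomainError(CamqaError):
    """A value lies outside its documented domain."""


class InsufficientDataError(CamqaError):
    """Not enough data to derive a potential or train a model."""


class IncompleteScoreError(CamqaError):
    """A model entered a comparison without all required scores."""


class IncompleteMatrixError(CamqaError):
    """A pairwise similarity matrix is missing an entry."""


class StateError(CamqaError):
    """An object was used before it was ready (e.g. untrained model)."""


class AmbiguousAxisError(GeometryError):
    """The gyration tensor is too isotropic to define a ring axis."""


class EmptyInputError(CamqaError):
    """An operation received an empty collection."""


class RunError(CamqaError):
    """Every model in a batch failed."""
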
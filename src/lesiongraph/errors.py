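"""Exception hierarchy for the lesiongraph pipeline."""


class LesionGraphError(Exception):
    """Base class for all lesiongraph errors."""


class CoordinateError(LesionGraphError):
    """A polygon vertex falls outside the image bounds."""


class AnnotationError(LesionGraphError):
    """A polygon annotation is degenerate (<3 vertices or collinear)."""


class GenerationError(LesionGraphError):
    """A synthetic case could not be generated for the requested profile."""


class PairingError(LesionGraphError):
    """Image and mask shapes disagree."""


class EmptyMaskError(LesionGraphError):
    """A mask contains no foreground regions."""


class UndefinedTextureError(LesionGraphError):
    """A region has too few co-occurring pixel pairs for texture statistics."""


class FormatError(LesionGraphError):
    """A serialized artifact violates its documented schema."""


class TableError(LesionGraphError):
    """A feature table violates its invariants (e.g. duplicate region ids)."""


class AugmentationError(LesionGraphError):
    """Graph augmentation preconditions are not met."""


class ShapeError(LesionGraphError):
    """Array dimensions are incompatible."""


class TrainingError(LesionGraphError):
    """Training diverged; carries the history accumulated so far."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class StratificationError(LesionGraphError):
    """A stratified split is infeasible for the given class counts."""


class OrphanError(LesionGraphError):
    """Graphs without a mask/image counterpart; lists the offending stems."""

    def __init__(self, message, orphans=()):
        super().__init__(message)
        self.orphans = list(orphans)


class DependencyError(LesionGraphError):
    """A pipeline stage is missing an upstream artifact."""
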
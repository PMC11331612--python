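"""Exception types shared across the package."""


class MtCladesError(Exception):
    """Base class for all package errors."""


class InvalidNameError(MtCladesError, ValueError):
    """A haplogroup label cannot be parsed (empty, or not starting with A-Z)."""


class UngroupableNameError(MtCladesError, ValueError):
    """A name cannot be placed in the requested grouping (e.g. bare "L" under SCL)."""


class UnmappedNameError(MtCladesError, KeyError):
    """A name matched no prefix in a custom cluster map and no default was given."""


class HierarchyLookupError(MtCladesError, KeyError):
    """A haplogroup name does not resolve to a node of the hierarchy."""


class NewickError(MtCladesError, ValueError):
    """Malformed Newick input (syntax, duplicate leaves, bad branch lengths)."""


class InvalidThresholdError(MtCladesError, ValueError):
    """A clustering threshold or threshold ladder violates its contract."""


class LevelConfigError(MtCladesError, ValueError):
    """A macro/meso/micro level threshold is absent from the ladder or mis-ordered."""


class UndefinedDistanceError(MtCladesError, ValueError):
    """A sequence pair shares no comparable alignment sites."""


class MaskError(MtCladesError, ValueError):
    """A masking specification cannot be applied to the alignment."""
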
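"""Exception hierarchy for physofrac."""


class PhysofracError(Exception):
    """Base class for all physofrac errors."""


class SchemaError(PhysofracError):
    """A table is missing required columns, samples, or metadata."""


class DataError(PhysofracError):
    """Values violate a data contract (negative counts, bad labels, ...)."""


class FormatError(PhysofracError):
    """A file could not be parsed (malformed Newick, bad TSV, ...)."""


class InvalidArgument(PhysofracError, ValueError):
    """An argument is outside its documented domain."""


class InvalidDesign(PhysofracError):
    """A statistical design is degenerate (single group, missing control, ...)."""


class DegenerateFraction(PhysofracError):
    """A sorted fraction has zero in-gate probability mass."""


class UnreachableTarget(PhysofracError):
    """A calibration target cannot be reached by the available parameters."""
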
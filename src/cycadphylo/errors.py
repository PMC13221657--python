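"""Exception hierarchy shared across the pipeline.

Every error raised on bad user input derives from :class:`CycadPhyloError`
so callers (and the CLI) can distinguish validation failures (exit status 1)
from genuine internal errors (exit status 2).
"""


class CycadPhyloError(Exception):
    """Base class for all validation and consistency errors."""


class AlignmentShapeError(CycadPhyloError):
    """Alignment rows have unequal lengths."""


class AlphabetError(CycadPhyloError):
    """A sequence contains a character outside the amino-acid alphabet."""


class NewickParseError(CycadPhyloError):
    """Malformed Newick input; message carries the character offset."""


class TreeValidationError(CycadPhyloError):
    """A parsed tree violates an invariant (duplicate tips, negative lengths)."""


class PartitionSchemeError(CycadPhyloError):
    """Partition ranges overlap, leave a gap, or fail to cover the matrix."""


class CalibrationError(CycadPhyloError):
    """A calibration row is invalid or cannot be satisfied."""


class ConsistencyError(CycadPhyloError):
    """Tree tips and alignment rows disagree."""


class InputError(CycadPhyloError):
    """Generic invalid argument to a pipeline operation."""


class IdentifiabilityError(CycadPhyloError):
    """Dating problem has no finite maximum-age constraint anywhere."""
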
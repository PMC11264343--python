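"""Exception hierarchy shared across the package."""


class MastphyloError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MastphyloError, ValueError):
    """An input violates a documented precondition."""


class DegenerateInputError(InvalidInputError):
    """Input is formally valid but carries no usable information
    (constant trait, monomorphic binary state, zero contrast variance)."""


class TreeError(MastphyloError, ValueError):
    """A phylogeny fails validation (duplicate tips, missing branch lengths...)."""


class ConvergenceError(MastphyloError, RuntimeError):
    """An optimiser failed and the caller asked for a hard failure."""
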
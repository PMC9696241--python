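"""Exception hierarchy for clonotyper.

Every refusal the pipeline can make raises a subclass of
:class:`ClonotyperError`, so callers (including the CLI) can separate
computational refusals from usage/IO problems.
"""


class ClonotyperError(Exception):
    """Base class for all pipeline errors."""


class EmptyInputError(ClonotyperError):
    """An input file or collection contained no usable records."""


class RaggedAlignmentError(ClonotyperError):
    """A FASTA alignment contained records of unequal length."""


class AlphabetError(ClonotyperError):
    """A character state fell outside the accepted alphabet."""


class TableParseError(ClonotyperError):
    """A tabular input cell could not be interpreted; carries coordinates."""

    def __init__(self, message, sample=None, character=None):
        super().__init__(message)
        self.sample = sample
        self.character = character


class RecodeError(ClonotyperError):
    """A matrix was in the wrong coding state for the requested recode."""


class SampleMismatchError(ClonotyperError):
    """Sample sets of matrices to merge (or peaks vs metadata) disagree."""


class MetadataError(ClonotyperError):
    """Sample metadata is inconsistent (e.g. dangling replicate pointer)."""


class UndefinedDistanceError(ClonotyperError):
    """A pairwise distance is undefined (no mutually unambiguous sites)."""

    def __init__(self, message, pairs=()):
        super().__init__(message)
        self.pairs = list(pairs)


class ConfigError(ClonotyperError):
    """A simulation or run configuration is infeasible."""
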
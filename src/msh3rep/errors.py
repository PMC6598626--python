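"""Exception hierarchy shared by all pipeline stages."""


class Msh3RepError(Exception):
    """Base class for all errors raised by this package."""


class LocusError(Msh3RepError):
    """Inconsistent locus description (unknown unit/allele/variant, bad invariant)."""


class ConfigError(Msh3RepError):
    """Invalid simulation or run configuration (exit code 2 at the CLI)."""


class QCError(Msh3RepError):
    """Malformed or empty FASTQ input encountered during quality control."""


class MergeError(Msh3RepError):
    """Unpaired or inconsistent paired-end FASTQ input."""


class AlignmentError(Msh3RepError):
    """Empty query/reference or an empty reference bank."""


class NoCallError(Msh3RepError):
    """Genotype could not be called (insufficient unambiguous read depth)."""


class UndefinedIndexError(Msh3RepError):
    """Somatic-instability index undefined (e.g. zero reads at the progenitor length)."""


class NotEstimableError(Msh3RepError):
    """Regression design rank-deficient or degenerate where an exception is required."""


class StageError(Msh3RepError):
    """A pipeline stage failed (exit code 3 at the CLI); partial outputs are retained."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
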
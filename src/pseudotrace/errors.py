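"""Exception hierarchy.

Every error raised by the package derives from :class:`PseudotraceError` so
callers (and the CLI, which maps error classes to exit codes) can distinguish
input problems from genuine bugs.
"""


class PseudotraceError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(PseudotraceError):
    """Rows of an exon alignment do not all have the same column count."""


class AlphabetError(PseudotraceError):
    """A residue outside {A,C,G,T,N, IUPAC ambiguity codes, '-'} was seen."""


class RoleError(PseudotraceError):
    """A taxon has no reference/target role, or a role set is degenerate."""


class ModelConsistencyError(PseudotraceError):
    """Alignments disagree with the gene model (lengths, phases, native stop)."""


class TaxonError(PseudotraceError):
    """A requested taxon is not present in the alignment."""


class ClassificationError(PseudotraceError):
    """A record of the wrong class was passed to an operation."""


class TreeError(PseudotraceError):
    """Tree is malformed: duplicate tips, missing lengths, not ultrametric."""


class LabelError(PseudotraceError):
    """A tip or node label is not present in the tree."""


class ConfigError(PseudotraceError):
    """A simulation or run configuration is internally inconsistent."""


class LesionSpecError(PseudotraceError):
    """A planted-lesion descriptor falls outside the exon bounds."""


class FormatError(PseudotraceError):
    """An input file is missing or cannot be parsed in the expected format."""
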
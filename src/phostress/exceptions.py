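"""Exception hierarchy shared across phostress modules."""


class PhostressError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhostressError):
    """Malformed input text (bad TSV/FASTA/Newick syntax, unknown symbols)."""


class CoordinateError(PhostressError):
    """Feature coordinates outside the contig or otherwise inconsistent."""


class NewickError(FormatError):
    """Unparseable or invalid Newick (unbalanced parentheses, duplicate leaves)."""


class UnknownGeneError(PhostressError, KeyError):
    """A gene/feature id was requested that the annotation does not contain."""


class ConfigurationError(PhostressError):
    """A simulation or pipeline configuration value is out of range."""


class DesignError(PhostressError):
    """An experimental design cannot support the requested test."""


class InsufficientDataError(PhostressError):
    """Too few observations for the requested estimate."""


class DegenerateInputError(PhostressError):
    """Statistically degenerate input (zero variance, all-zero table)."""
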
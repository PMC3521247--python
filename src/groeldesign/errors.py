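"""Exception hierarchy. All package errors derive from :class:`GroelDesignError`."""


class GroelDesignError(Exception):
    """Base class for all errors raised by groeldesign."""


class FastaFormatError(GroelDesignError):
    """Malformed or empty FASTA input."""


class SequenceValidationError(GroelDesignError):
    """A sequence contains characters outside the 20 canonical residues."""


class MutationParseError(GroelDesignError):
    """A mutation code does not match <wild><position><new> with position >= 1."""


class MutationConsistencyError(GroelDesignError):
    """A mutation's wild residue disagrees with the sequence, or is out of range."""


class ParameterError(GroelDesignError):
    """An operation parameter is out of its documented domain."""


class ComparisonError(GroelDesignError):
    """Two profiles cannot be compared (length or parameter mismatch)."""
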
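"""FASTA I/O, sequence validation and point-mutation nomenclature.

Sequences are plain upper-case strings over the 20 canonical one-letter
amino-acid codes; residue numbering is 1-based over the full sequence as
given in the FASTA (so a code like ``D17I`` refers to the 17th residue of
the record, with no signal-peptide offset handling).  Non-canonical codes
(B, J, O, U, X, Z, ...) are rejected rather than silently remapped, because
every downstream score needs a defined hydropathy value for every residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    FastaFormatError,
    MutationConsistencyError,
    MutationParseError,
    SequenceValidationError,
)
from .scales import CANONICAL_AMINO_ACIDS

_CANONICAL_SET = frozenset(CANONICAL_AMINO_ACIDS)
_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def validate_sequence(sequence: str, record_id: str = "<sequence>") -> str:
    """Upper-case *sequence*, strip a terminal ``*`` stop, check the alphabet.

    Returns the normalized sequence; raises
    :class:`~groeldesign.errors.SequenceValidationError` naming the record and
    the 1-based position of the first offending character.
    """
    seq = sequence.upper().removesuffix("*")
    if not seq:
        raise FastaFormatError(f"record {record_id!r} has an empty sequence")
    for pos, aa in enumerate(seq, start=1):
        if aa not in _CANONICAL_SET:
            raise SequenceValidationError(
                f"record {record_id!r}: non-canonical residue {aa!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence with its identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, self.id))

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Inclusive 1-based slice, matching the coordinate convention of hits."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise MutationConsistencyError(
                f"positions [{start}, {end}] out of range for {self.id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True, order=True)
class Mutation:
    """A single point substitution in ``D17I`` one-letter form (1-based)."""

    position: int
    wild_residue: str
    new_residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")
        for aa in (self.wild_residue, self.new_residue):
            if aa not in _CANONICAL_SET:
                raise MutationParseError(f"non-canonical residue {aa!r} in mutation")
        if self.wild_residue == self.new_residue:
            raise MutationParseError(
                f"silent substitution {self.wild_residue}{self.position}"
                f"{self.new_residue} (wild and new residue identical)"
            )

    @property
    def code(self) -> str:
        return f"{self.wild_residue}{self.position}{self.new_residue}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_mutation_code(code: str) -> Mutation:
    """Parse one ``<wild><position><new>`` token, e.g. ``"D17I"``."""
    m = _MUTATION_RE.match(code.strip())
    if m is None:
        raise MutationParseError(f"malformed mutation code {code!r}")
    wild, pos, new = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return Mutation(position=pos, wild_residue=wild, new_residue=new)


def parse_mutation_codes(text: str) -> tuple[Mutation, ...]:
    """Parse whitespace- or comma-separated codes, e.g. ``"D17I E20I"``."""
    tokens = [t for t in re.split(r"[,\s]+", text.strip()) if t]
    return tuple(parse_mutation_code(t) for t in tokens)


def format_mutations(mutations: Iterable[Mutation]) -> str:
    """Space-joined codes in ascending position order (``"D17I E20I"``)."""
    return " ".join(m.code for m in sorted(mutations, key=lambda m: m.position))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly wrapped, possibly multi-record) FASTA file.

    Sequences are upper-cased and a terminal ``*`` is stripped; record order
    is preserved.  An empty file is a format error.
    """
    path = Path(path)
    with open(path) as handle:  # missing file propagates as FileNotFoundError
        records = [
            ProteinRecord(id=r.id, sequence=str(r.seq), description=r.description)
            for r in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (round-trips exactly with read_fasta)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta-2line")


def apply_mutations(
    record: ProteinRecord, mutations: Iterable[Mutation]
) -> ProteinRecord:
    """Apply point substitutions to a record.

    Every mutation's wild residue must match the sequence at its (1-based)
    position and positions must be pairwise distinct.  The returned record's
    id is suffixed with the applied codes; an empty mutation set returns an
    identical record.
    """
    muts = sorted(mutations, key=lambda m: m.position)
    if not muts:
        return replace(record)
    positions = [m.position for m in muts]
    if len(set(positions)) != len(positions):
        raise MutationConsistencyError(f"duplicate mutation positions in {positions}")
    seq = list(record.sequence)
    for m in muts:
        if m.position > len(seq):
            raise MutationConsistencyError(
                f"{m.code}: position {m.position} beyond sequence of length {len(seq)}"
            )
        found = seq[m.position - 1]
        if found != m.wild_residue:
            raise MutationConsistencyError(
                f"{m.code}: expected {m.wild_residue!r} at position {m.position} "
                f"of {record.id!r}, found {found!r}"
            )
        seq[m.position - 1] = m.new_residue
    suffix = "_".join(m.code for m in muts)
    return ProteinRecord(
        id=f"{record.id}_{suffix}",
        sequence="".join(seq),
        description=record.description,
    )
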
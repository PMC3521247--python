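"""Double-mutant library design over a hydrophobic patch.

The design rule mirrors the engineering procedure this package implements:
pick the two least-hydrophobic positions of the suggested patch (lowest
Kyte–Doolittle values, leftmost on ties) and substitute every ordered pair
from the hydrophobic alphabet {I, L, V}, yielding nine double mutants per
patch.  Single mutants are not generated by default because a single
substitution moves the patch GRAVY too little to matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

from .errors import ParameterError
from .hydropathy import delta_gravy, gravy
from .scales import KYTE_DOOLITTLE, HydropathyScale
from .sequence_io import Mutation, ProteinRecord, apply_mutations, format_mutations

DEFAULT_ALPHABET = "ILV"


@dataclass(frozen=True)
class MutantVariant:
    """A double-substituted patch with its hydropathy bookkeeping.

    ``mutations`` carry absolute 1-based protein coordinates (patch offset 2
    at patch_start 16 is residue 17, i.e. ``D17I``).
    """

    parent_id: str
    patch_start: int
    wild_patch: str
    mutant_patch: str
    mutations: tuple[Mutation, ...]
    patch_gravy: float
    delta_gravy: float

    @property
    def mutation_codes(self) -> str:
        return format_mutations(self.mutations)


def select_mutable_positions(
    patch: str, k: int = 2, scale: HydropathyScale = KYTE_DOOLITTLE
) -> tuple[int, ...]:
    """The k positions (1-based within the patch) with lowest hydropathy.

    Ties break to the leftmost position; the result is sorted ascending.
    """
    if not (1 <= k <= len(patch)):
        raise ParameterError(f"k={k} out of range for patch of length {len(patch)}")
    ranked = sorted(range(1, len(patch) + 1), key=lambda p: (scale[patch[p - 1]], p))
    return tuple(sorted(ranked[:k]))


def enumerate_double_mutants(
    patch: str,
    positions: Sequence[int] | None = None,
    alphabet: str = DEFAULT_ALPHABET,
    parent_id: str = "",
    patch_start: int = 1,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> list[MutantVariant]:
    """All |alphabet|² double mutants of *patch* at two positions.

    Positions default to the two lowest-hydropathy sites.  Enumeration is in
    Cartesian order with the first position cycling slowest and the alphabet
    in its given order (I, L, V by default), so reports are diff-stable.
    """
    if not alphabet:
        raise ParameterError("substitution alphabet must be non-empty")
    if positions is None:
        positions = select_mutable_positions(patch, k=2, scale=scale)
    if len(positions) != 2 or positions[0] == positions[1]:
        raise ParameterError(f"need two distinct patch positions, got {positions}")
    for p in positions:
        if not (1 <= p <= len(patch)):
            raise ParameterError(f"patch position {p} out of range 1..{len(patch)}")
        if patch[p - 1] in alphabet:
            raise ParameterError(
                f"wild residue {patch[p - 1]!r} at patch position {p} is already "
                f"in the substitution alphabet {alphabet!r}; every variant must "
                f"differ from the wild patch at exactly two positions"
            )
    wild_gravy = gravy(patch, scale).gravy
    variants: list[MutantVariant] = []
    for subs in product(alphabet, repeat=len(positions)):
        seq = list(patch)
        muts = []
        for pos, new in zip(positions, subs):
            muts.append(
                Mutation(
                    position=patch_start + pos - 1,
                    wild_residue=patch[pos - 1],
                    new_residue=new,
                )
            )
            seq[pos - 1] = new
        mutant_patch = "".join(seq)
        g = gravy(mutant_patch, scale).gravy
        variants.append(
            MutantVariant(
                parent_id=parent_id,
                patch_start=patch_start,
                wild_patch=patch,
                mutant_patch=mutant_patch,
                mutations=tuple(muts),
                patch_gravy=g,
                delta_gravy=g - wild_gravy,
            )
        )
    return variants


def lift_to_protein(
    variant: MutantVariant, record: ProteinRecord
) -> tuple[ProteinRecord, str]:
    """Apply a patch variant to its full-length parent record.

    Returns the mutated record and the absolute mutation codes
    (``"D17I E20I"``).  The wild patch must occur in *record* at the
    variant's patch_start, and the variant must actually differ from wild.
    """
    if not variant.mutations:
        raise ParameterError("variant is identical to the wild patch")
    end = variant.patch_start + len(variant.wild_patch) - 1
    found = record.subsequence(variant.patch_start, end)
    if found != variant.wild_patch:
        from .errors import MutationConsistencyError

        raise MutationConsistencyError(
            f"record {record.id!r} has {found!r} at positions "
            f"[{variant.patch_start}, {end}], expected {variant.wild_patch!r}"
        )
    mutated = apply_mutations(record, variant.mutations)
    return mutated, variant.mutation_codes


def check_delta(variant: MutantVariant) -> float:
    """Recompute ΔGRAVY from the patches (diagnostic cross-check)."""
    return delta_gravy(variant.wild_patch, variant.mutant_patch)
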
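"""Seeded synthetic proteins with embedded motif-like patches.

Real GroEL non-substrate sequences are deliberately not bundled: the only
sequence facts the analyses pin down are the patch contents and their
absolute coordinates, so the fixtures preserve exactly those, embedded in a
reproducible low-hydropathy random background.  All randomness goes through
``numpy.random.default_rng`` (PCG64) with an explicit seed, so fixture
generation is platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .sequence_io import ProteinRecord, validate_sequence

# Low-hydropathy residues; keeps random backgrounds dissimilar from the
# hydrophobic reference motif so embedded patches dominate the scan.
DEFAULT_BACKGROUND = "ASTNQDEKR"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    length: int
    embedded_patch: str
    patch_start: int  # 1-based
    background_alphabet: str = DEFAULT_BACKGROUND
    decoy_identities: tuple[float, ...] = field(default=())
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        validate_sequence(self.embedded_patch, "embedded_patch")
        validate_sequence(self.background_alphabet, "background_alphabet")
        if self.patch_start < 1:
            raise ParameterError("patch_start must be >= 1")
        if self.patch_start + len(self.embedded_patch) - 1 > self.length:
            raise ParameterError(
                f"patch of length {len(self.embedded_patch)} at position "
                f"{self.patch_start} does not fit in length {self.length}"
            )
        for f in self.decoy_identities:
            if not (0.0 <= f <= 1.0):
                raise ParameterError(f"decoy identity {f} outside [0, 1]")


def _decoy(motif: str, identity: float, rng: np.random.Generator, background: str) -> str:
    """A motif-length peptide sharing ~identity of its positions with the motif."""
    n_keep = round(identity * len(motif))
    keep = set(rng.choice(len(motif), size=n_keep, replace=False).tolist())
    out = []
    bg = [aa for aa in background]
    for i, aa in enumerate(motif):
        if i in keep:
            out.append(aa)
        else:
            choices = [b for b in bg if b != aa]
            out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def synth_protein(spec: FixtureSpec) -> ProteinRecord:
    """Deterministically generate the protein described by *spec*.

    Background residues are drawn uniformly from the background alphabet;
    the patch is written verbatim at ``patch_start``.  Decoys (windows with
    controlled identity to the patch) are placed left-to-right after the
    patch, separated by at least one background residue.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(spec.background_alphabet))
    seq = list(alphabet[rng.integers(len(alphabet), size=spec.length)])
    start0 = spec.patch_start - 1
    seq[start0 : start0 + len(spec.embedded_patch)] = list(spec.embedded_patch)

    cursor = start0 + len(spec.embedded_patch) + 1
    for identity in spec.decoy_identities:
        d = _decoy(spec.embedded_patch, identity, rng, spec.background_alphabet)
        if cursor + len(d) > spec.length:
            raise ParameterError("decoys do not fit in the requested length")
        seq[cursor : cursor + len(d)] = list(d)
        cursor += len(d) + 1

    return ProteinRecord(
        id=spec.record_id,
        sequence="".join(seq),
        description=f"synthetic fixture seed={spec.seed}",
    )


def alla_like_fixture(seed: int = 11, length: int = 120) -> ProteinRecord:
    """Synthetic stand-in for ureidoglycolate hydrolase: GDVIETQ at 16–22.

    The absolute coordinates make the canonical mutation labels (D17, E20)
    line up with the real protein's numbering.
    """
    return synth_protein(
        FixtureSpec(
            seed=seed,
            length=length,
            embedded_patch="GDVIETQ",
            patch_start=16,
            record_id="ALLA_like_synthetic",
        )
    )


def hcha_like_fixture(seed: int = 12, length: int = 120) -> ProteinRecord:
    """Synthetic stand-in for Hsp31: GKLFSTG at 62–68 (K63, S66 numbering)."""
    return synth_protein(
        FixtureSpec(
            seed=seed,
            length=length,
            embedded_patch="GKLFSTG",
            patch_start=62,
            record_id="HCHA_like_synthetic",
        )
    )
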
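"""Residue-level scales used throughout the package, shipped as named data assets.

Two scales are bundled:

* ``KYTE_DOOLITTLE`` — the hydropathy index of Kyte & Doolittle (1982),
  spanning −4.5 (Arg) to +4.5 (Ile).  GRAVY and every hydropathy profile in
  this package are means over this scale.
* ``CHOU_FASMAN_BETA`` — the Chou–Fasman β-sheet conformational preference
  P(β) (reported ×100), used by the aggregation-propensity surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

CANONICAL_AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_KD: Mapping[str, float] = MappingProxyType({
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
})

# Chou-Fasman P(beta), x100. Glu is the weakest sheet former, Val the strongest.
_CF_BETA: Mapping[str, float] = MappingProxyType({
    "A": 83.0, "R": 93.0, "N": 89.0, "D": 54.0, "C": 119.0,
    "Q": 110.0, "E": 37.0, "G": 75.0, "H": 87.0, "I": 160.0,
    "L": 130.0, "K": 74.0, "M": 105.0, "F": 138.0, "P": 55.0,
    "S": 75.0, "T": 119.0, "W": 137.0, "Y": 147.0, "V": 170.0,
})


@dataclass(frozen=True)
class HydropathyScale:
    """A named per-residue scale over the 20 canonical amino acids."""

    name: str
    values: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.values) != set(CANONICAL_AMINO_ACIDS):
            raise ValueError(
                f"scale {self.name!r} must define exactly the 20 canonical "
                f"residues, got {sorted(self.values)}"
            )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(
                f"residue {residue!r} not in scale {self.name!r}"
            ) from None

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())


KYTE_DOOLITTLE = HydropathyScale(name="kyte-doolittle", values=_KD)
CHOU_FASMAN_BETA = HydropathyScale(name="chou-fasman-beta", values=_CF_BETA)
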
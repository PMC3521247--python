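"""GRAVY, ΔGRAVY and sliding-window hydropathy profiles.

GRAVY (grand average of hydropathicity) is the sum of per-residue
Kyte–Doolittle hydropathy indices divided by the number of residues; higher
values mean a more hydrophobic, less soluble peptide.  Displayed values are
truncated (not rounded) to three decimals, matching the convention of the
reference tables this package reproduces; full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .errors import ParameterError, SequenceValidationError
from .scales import KYTE_DOOLITTLE, HydropathyScale
from .sequence_io import ProteinRecord


def display_value(value: float, ndigits: int = 3) -> float:
    """Truncate *value* toward zero at *ndigits* decimals for display.

    1.928571 -> 1.928 and −0.414285 -> −0.414.  Float noise below 1e-9 is
    removed first so exact thousandths are not nudged across the boundary.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(round(value, 9))).quantize(q, rounding=ROUND_DOWN))


def display_percent(value: float) -> float:
    """Round a percentage half-up to one decimal (42.857 -> 42.9)."""
    return float(Decimal(str(round(value, 9))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GravyResult:
    sequence: str
    gravy: float
    n_residues: int

    @property
    def display(self) -> float:
        """The value as printed in reports: truncated to 3 decimals."""
        return display_value(self.gravy)


def _residue_values(peptide: str, scale: HydropathyScale) -> list[float]:
    try:
        return [scale[aa] for aa in peptide]
    except KeyError as exc:
        raise SequenceValidationError(str(exc)) from None


def gravy(peptide: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> GravyResult:
    """Mean hydropathy of *peptide* under *scale* (default Kyte–Doolittle)."""
    if not peptide:
        raise ParameterError("GRAVY of an empty peptide is undefined")
    values = _residue_values(peptide.upper(), scale)
    return GravyResult(
        sequence=peptide.upper(),
        gravy=math.fsum(values) / len(values),
        n_residues=len(values),
    )


def delta_gravy(
    wild_patch: str, mutant_patch: str, scale: HydropathyScale = KYTE_DOOLITTLE
) -> float:
    """gravy(mutant) − gravy(wild) for two equal-length patches."""
    if len(wild_patch) != len(mutant_patch):
        raise ParameterError(
            f"patch lengths differ: {len(wild_patch)} vs {len(mutant_patch)}"
        )
    return gravy(mutant_patch, scale).gravy - gravy(wild_patch, scale).gravy


def display_delta(
    wild_patch: str, mutant_patch: str, scale: HydropathyScale = KYTE_DOOLITTLE
) -> float:
    """ΔGRAVY as printed in reports: difference of the *displayed* GRAVYs.

    Report columns quote GRAVYs truncated to 3 decimals, and the increase
    column is their difference (so it can differ from the full-precision
    ΔGRAVY by one unit in the last place).
    """
    if len(wild_patch) != len(mutant_patch):
        raise ParameterError(
            f"patch lengths differ: {len(wild_patch)} vs {len(mutant_patch)}"
        )
    return round(
        display_value(gravy(mutant_patch, scale).gravy)
        - display_value(gravy(wild_patch, scale).gravy),
        3,
    )


def sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over a centered window, truncated (shrunk) at the sequence ends.

    The returned track has the same length as the input; position i averages
    values[max(0, i-h) : i+h+1] with h = window // 2.  Each window is summed
    locally (no running prefix sum), so positions whose windows exclude an
    edit are bit-identical before and after it.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window}")
    n = len(values)
    if window > n:
        raise ParameterError(f"window {window} exceeds sequence length {n}")
    h = window // 2
    out = np.empty(n, dtype=float)
    interior = np.lib.stride_tricks.sliding_window_view(values, window)
    out[h : n - h] = interior.sum(axis=1) / window
    for i in range(h):
        out[i] = values[: i + h + 1].sum() / (i + h + 1)
        out[n - 1 - i] = values[n - 1 - i - h :].sum() / (i + h + 1)
    return out


def hydropathy_profile(
    record: ProteinRecord,
    window: int = 7,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> np.ndarray:
    """Per-residue mean hydropathy over a centered, edge-truncated window."""
    values = np.asarray(_residue_values(record.sequence, scale))
    return sliding_mean(values, window)


def profile_to_tsv(track: np.ndarray, path: str | Path) -> None:
    """Export a profile as 2-column TSV: 1-based position, value."""
    with open(path, "w") as fh:
        fh.write("position\tvalue\n")
        for i, v in enumerate(track, start=1):
            fh.write(f"{i}\t{v:.6g}\n")
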
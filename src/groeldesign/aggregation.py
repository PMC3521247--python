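"""Per-residue β-aggregation-propensity profiles on a 0–100 scale.

This is a transparent, self-contained surrogate for full statistical-
mechanics aggregation predictors.  Each residue gets a raw score in [0, 1]:

    raw(aa) = clamp01( w_h · h(aa) + w_b · b(aa) − w_c · |q(aa)| )

where h is the min–max-normalized Kyte–Doolittle hydropathy, b the
min–max-normalized Chou–Fasman β-sheet propensity, and |q| a charge penalty
(1 for D/E/K/R, 0.5 for H, 0 otherwise).  Proline and glycine are forced to
zero as β-breakers.  The profile is 100 × the mean raw score over a
centered, edge-truncated window; aggregation-prone segments ("peaks") are
maximal runs of at least ``min_run`` residues above a threshold.

The surrogate's contract is qualitative and monotone: substituting a
charged/polar residue by a hydrophobic one never lowers the profile, so
patch double mutants produce new or heightened peaks around the patch.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .errors import ComparisonError, ParameterError
from .hydropathy import sliding_mean
from .scales import CANONICAL_AMINO_ACIDS, CHOU_FASMAN_BETA, KYTE_DOOLITTLE
from .sequence_io import ProteinRecord

DEFAULT_WEIGHTS = (0.5, 0.4, 0.1)  # (w_h, w_b, w_c)
DEFAULT_WINDOW = 5
DEFAULT_THRESHOLD = 20.0
DEFAULT_MIN_RUN = 5

_CHARGE = {"D": 1.0, "E": 1.0, "K": 1.0, "R": 1.0, "H": 0.5}
_BETA_BREAKERS = frozenset("PG")


def _raw_scores(weights: tuple[float, float, float]) -> Mapping[str, float]:
    w_h, w_b, w_c = weights
    kd_min, kd_span = KYTE_DOOLITTLE.min, KYTE_DOOLITTLE.max - KYTE_DOOLITTLE.min
    cf_min, cf_span = CHOU_FASMAN_BETA.min, CHOU_FASMAN_BETA.max - CHOU_FASMAN_BETA.min
    table = {}
    for aa in CANONICAL_AMINO_ACIDS:
        if aa in _BETA_BREAKERS:
            table[aa] = 0.0
            continue
        h = (KYTE_DOOLITTLE[aa] - kd_min) / kd_span
        b = (CHOU_FASMAN_BETA[aa] - cf_min) / cf_span
        q = _CHARGE.get(aa, 0.0)
        table[aa] = min(1.0, max(0.0, w_h * h + w_b * b - w_c * q))
    return MappingProxyType(table)


_DEFAULT_TABLE = _raw_scores(DEFAULT_WEIGHTS)


def residue_agg_score(
    aa: str, weights: tuple[float, float, float] = DEFAULT_WEIGHTS
) -> float:
    """Raw per-residue aggregation score in [0, 1]."""
    table = _DEFAULT_TABLE if weights == DEFAULT_WEIGHTS else _raw_scores(weights)
    try:
        return table[aa]
    except KeyError:
        raise ParameterError(f"unknown residue {aa!r}") from None


@dataclass(frozen=True)
class AggregationProfile:
    protein_id: str
    values: np.ndarray  # per-residue, in [0, 100]
    window: int
    threshold: float
    min_run: int
    peaks: tuple[tuple[int, int, float], ...]  # (start, end, max) 1-based inclusive

    def __len__(self) -> int:
        return len(self.values)


def _call_peaks(
    values: np.ndarray, threshold: float, min_run: int
) -> tuple[tuple[int, int, float], ...]:
    peaks = []
    start = None
    for i, v in enumerate(values):
        if v > threshold:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_run:
                peaks.append((start + 1, i, float(values[start:i].max())))
            start = None
    if start is not None and len(values) - start >= min_run:
        peaks.append((start + 1, len(values), float(values[start:].max())))
    return tuple(peaks)


def aggregation_profile(
    record: ProteinRecord,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> AggregationProfile:
    """Windowed 0–100 aggregation-propensity track with called peaks."""
    table = _DEFAULT_TABLE if weights == DEFAULT_WEIGHTS else _raw_scores(weights)
    raw = np.array([table[aa] for aa in record.sequence])
    values = 100.0 * sliding_mean(raw, window)
    return AggregationProfile(
        protein_id=record.id,
        values=values,
        window=window,
        threshold=threshold,
        min_run=min_run,
        peaks=_call_peaks(values, threshold, min_run),
    )


@dataclass(frozen=True)
class PeakDelta:
    """Peak-level differences of a mutant profile relative to wild type."""

    new_peaks: tuple[tuple[int, int, float], ...]
    increased_peaks: tuple[tuple[int, int, float], ...]
    max_gain: float  # max over positions of (mutant - wild)

    @property
    def n_new(self) -> int:
        return len(self.new_peaks)

    @property
    def n_increased(self) -> int:
        return len(self.increased_peaks)


def _overlaps(a: tuple[int, int, float], b: tuple[int, int, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_profiles(wild: AggregationProfile, mutant: AggregationProfile) -> PeakDelta:
    """Classify mutant peaks as new or increased relative to the wild profile."""
    if len(wild) != len(mutant):
        raise ComparisonError(
            f"profile lengths differ: {len(wild)} vs {len(mutant)}"
        )
    if (wild.window, wild.threshold, wild.min_run) != (
        mutant.window, mutant.threshold, mutant.min_run,
    ):
        raise ComparisonError("profiles were computed with different parameters")
    new_peaks = []
    increased = []
    for mp in mutant.peaks:
        overlapping = [wp for wp in wild.peaks if _overlaps(mp, wp)]
        if not overlapping:
            new_peaks.append(mp)
        elif mp[2] > max(wp[2] for wp in overlapping):
            increased.append(mp)
    max_gain = float(np.max(mutant.values - wild.values)) if len(wild) else 0.0
    return PeakDelta(
        new_peaks=tuple(new_peaks),
        increased_peaks=tuple(increased),
        max_gain=max_gain,
    )
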
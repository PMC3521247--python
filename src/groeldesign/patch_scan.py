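"""Motif-similarity scanning against the GroES mobile-loop patch.

The reference motif is ``GGIVLTG``, the segment of the GroES mobile loop
that contacts GroEL's apical domain.  Candidate windows of a protein are
scored by ungapped position-wise identity against the motif — the shorter
peptide slides along the longer at every full-overlap offset, and percent
correlation is 100 × identities / shorter length.  A deterministic
Smith–Waterman local aligner is provided as an optional cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ParameterError
from .hydropathy import display_percent, gravy
from .scales import KYTE_DOOLITTLE, HydropathyScale
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_MOTIF = "GGIVLTG"


@dataclass(frozen=True)
class PatchHit:
    """A candidate window on a protein with its similarity to the motif."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    patch: str
    percent_correlation: float  # displayed to 1 decimal
    n_identities: int
    patch_gravy: float


def ungapped_identity(query: str, motif: str) -> tuple[int, int, float]:
    """Best ungapped overlap of the shorter peptide along the longer.

    Returns ``(best_offset, n_identities, percent)`` where *percent* uses
    the shorter peptide's length as denominator and ties go to the smallest
    offset.  Symmetric in its arguments up to the sign of the offset.
    """
    if not query or not motif:
        raise ParameterError("peptides must be non-empty")
    short, long_ = (query, motif) if len(query) <= len(motif) else (motif, query)
    best_offset, best_n = 0, -1
    for offset in range(len(long_) - len(short) + 1):
        n = sum(a == b for a, b in zip(short, long_[offset : offset + len(short)]))
        if n > best_n:
            best_offset, best_n = offset, n
    return best_offset, best_n, 100.0 * best_n / len(short)


def scan_motif(
    record: ProteinRecord,
    motif: str = DEFAULT_MOTIF,
    min_len: int = 6,
    max_len: int = 8,
    top_k: int = 5,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> list[PatchHit]:
    """Score every window of each length in ``[min_len, max_len]`` against *motif*.

    Hits are sorted by (percent correlation desc, patch GRAVY desc, start asc,
    end asc) and truncated to *top_k*; exact-duplicate intervals are removed.
    A sequence shorter than *min_len* yields an empty result with a warning.
    """
    if not (1 <= min_len <= max_len <= len(motif) + 2):
        raise ParameterError(
            f"window lengths must satisfy 1 <= min_len <= max_len <= "
            f"{len(motif) + 2}, got [{min_len}, {max_len}]"
        )
    seq = record.sequence
    if len(seq) < min_len:
        logger.warning(
            "sequence %s (length %d) shorter than min_len %d; no hits",
            record.id, len(seq), min_len,
        )
        return []
    hits: dict[tuple[int, int], PatchHit] = {}
    for length in range(min_len, min(max_len, len(seq)) + 1):
        for start0 in range(len(seq) - length + 1):
            window = seq[start0 : start0 + length]
            _, n_id, percent = ungapped_identity(window, motif)
            key = (start0 + 1, start0 + length)
            hits[key] = PatchHit(
                protein_id=record.id,
                start=key[0],
                end=key[1],
                patch=window,
                percent_correlation=display_percent(percent),
                n_identities=n_id,
                patch_gravy=gravy(window, scale).gravy,
            )
    # GRAVY tie-break key is quantized so summation order cannot flip ties
    ordered = sorted(
        hits.values(),
        key=lambda h: (-h.percent_correlation, -round(h.patch_gravy, 9), h.start, h.end),
    )
    return ordered[:top_k]


def suggest_patch(
    record: ProteinRecord, hit: PatchHit, target_len: int = 7
) -> tuple[int, str]:
    """Extend (or trim) a hit to the fixed-length patch used for mutagenesis.

    The suggested patch is the *target_len*-residue window anchored at the
    hit's start, extended rightward and falling back leftward at the
    sequence end.  Returns ``(patch_start, patch)`` in 1-based coordinates.
    """
    n = len(record.sequence)
    if n < target_len:
        raise ParameterError(
            f"sequence {record.id!r} shorter than patch length {target_len}"
        )
    start = hit.start
    if start + target_len - 1 > n:
        start = n - target_len + 1
    return start, record.subsequence(start, start + target_len - 1)


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    aligned_query: str
    aligned_motif: str
    query_start: int  # 1-based start of the aligned region in the query
    motif_start: int
    n_identities: int
    percent_identity: float  # over aligned columns


def local_align(
    query: str,
    motif: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> LocalAlignment:
    """Smith–Waterman local alignment with linear gap penalty.

    Traceback is deterministic: on ties prefer diagonal, then up (gap in
    motif), then left; the highest-scoring cell is the first maximum in
    row-major order.
    """
    if not query or not motif:
        raise ParameterError("peptides must be non-empty")
    if not (gap <= 0 and mismatch <= 0 < match):
        raise ParameterError(
            f"require gap <= 0, mismatch <= 0 < match; got "
            f"match={match}, mismatch={mismatch}, gap={gap}"
        )
    nq, nm = len(query), len(motif)
    H = [[0.0] * (nm + 1) for _ in range(nq + 1)]
    best, best_ij = 0.0, (0, 0)
    for i in range(1, nq + 1):
        for j in range(1, nm + 1):
            diag = H[i - 1][j - 1] + (match if query[i - 1] == motif[j - 1] else mismatch)
            up = H[i - 1][j] + gap
            left = H[i][j - 1] + gap
            h = max(0.0, diag, up, left)
            H[i][j] = h
            if h > best:
                best, best_ij = h, (i, j)
    # traceback from the first maximal cell
    i, j = best_ij
    aq: list[str] = []
    am: list[str] = []
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        diag = H[i - 1][j - 1] + (match if query[i - 1] == motif[j - 1] else mismatch)
        if h == diag:
            aq.append(query[i - 1])
            am.append(motif[j - 1])
            i, j = i - 1, j - 1
        elif h == H[i - 1][j] + gap:
            aq.append(query[i - 1])
            am.append("-")
            i -= 1
        else:
            aq.append("-")
            am.append(motif[j - 1])
            j -= 1
    aq.reverse()
    am.reverse()
    n_cols = len(aq)
    n_id = sum(a == b and a != "-" for a, b in zip(aq, am))
    return LocalAlignment(
        score=best,
        aligned_query="".join(aq),
        aligned_motif="".join(am),
        query_start=i + 1,
        motif_start=j + 1,
        n_identities=n_id,
        percent_identity=100.0 * n_id / n_cols if n_cols else 0.0,
    )
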
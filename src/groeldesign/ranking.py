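"""Candidate filtering, ranking and the end-to-end design pipeline.

A designed double mutant qualifies as a GroEL-substrate candidate when its
patch GRAVY is at least that of the GroES mobile-loop motif (an optional
tolerance relaxes "at least" to "comparable").  Candidates are ranked by
patch GRAVY, then by aggregation-propensity gain, then by mutation code for
determinism.  Force-field energies are outside this package's scope, so the
GRAVY/aggregation key is the selection criterion; the report header says so.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import aggregation as agg
from .aggregation import AggregationProfile, PeakDelta, aggregation_profile, compare_profiles
from .errors import GroelDesignError, ParameterError
from .hydropathy import display_delta, display_value, gravy
from .mutagenesis import (
    DEFAULT_ALPHABET,
    MutantVariant,
    enumerate_double_mutants,
    lift_to_protein,
    select_mutable_positions,
)
from .patch_scan import DEFAULT_MOTIF, PatchHit, scan_motif, suggest_patch
from .sequence_io import ProteinRecord, read_fasta

logger = logging.getLogger(__name__)

REPORT_HEADER = (
    "# Ranking key: patch GRAVY desc, aggregation max-gain desc, mutation code asc.\n"
    "# Molecular-dynamics energies are not computed; GRAVY and aggregation gain\n"
    "# substitute for the stability leg of the selection.\n"
)


@dataclass(frozen=True)
class CandidateReport:
    variant: MutantVariant
    percent_correlation: float
    agg_delta: PeakDelta
    reference_gravy: float
    passes_gravy_filter: bool
    rank: int

    @property
    def mutation_codes(self) -> str:
        return self.variant.mutation_codes


def gravy_filter(
    variants: Sequence[MutantVariant],
    motif: str = DEFAULT_MOTIF,
    tolerance: float = 0.0,
) -> list[MutantVariant]:
    """Keep variants whose patch GRAVY >= gravy(motif) − tolerance."""
    cutoff = gravy(motif).gravy - tolerance
    return [v for v in variants if v.patch_gravy >= cutoff]


def rank_candidates(
    variants: Sequence[MutantVariant],
    deltas: Mapping[str, PeakDelta],
    percent_correlation: float = 0.0,
    motif: str = DEFAULT_MOTIF,
) -> list[CandidateReport]:
    """Deterministically rank filtered variants into CandidateReports.

    *deltas* maps each variant's mutation-code string to its PeakDelta; a
    missing profile is an input error.
    """
    ref = gravy(motif).gravy
    missing = [v.mutation_codes for v in variants if v.mutation_codes not in deltas]
    if missing:
        raise ParameterError(f"no aggregation delta for variants: {missing}")
    ordered = sorted(
        variants,
        key=lambda v: (-v.patch_gravy, -deltas[v.mutation_codes].max_gain, v.mutation_codes),
    )
    return [
        CandidateReport(
            variant=v,
            percent_correlation=percent_correlation,
            agg_delta=deltas[v.mutation_codes],
            reference_gravy=ref,
            passes_gravy_filter=v.patch_gravy >= ref,
            rank=i,
        )
        for i, v in enumerate(ordered, start=1)
    ]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the scan → mutate → score → rank pipeline."""

    motif: str = DEFAULT_MOTIF
    min_len: int = 6
    max_len: int = 8
    top_k: int = 5
    patch_len: int = 7
    alphabet: str = DEFAULT_ALPHABET
    window: int = agg.DEFAULT_WINDOW
    threshold: float = agg.DEFAULT_THRESHOLD
    min_run: int = agg.DEFAULT_MIN_RUN
    weights: tuple[float, float, float] = agg.DEFAULT_WEIGHTS
    tolerance: float = 0.0
    seed: int = 0
    outdir: str | None = None


@dataclass
class FamilyResult:
    """Per-protein outcome: the chosen patch and its ranked mutant family."""

    record: ProteinRecord
    hit: PatchHit
    patch_start: int
    patch: str
    variants: list[MutantVariant]
    wild_profile: AggregationProfile
    mutant_profiles: dict[str, AggregationProfile]
    deltas: dict[str, PeakDelta]
    candidates: list[CandidateReport]


@dataclass
class PipelineResult:
    config: PipelineConfig
    families: list[FamilyResult] = field(default_factory=list)

    def hits_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": f.hit.protein_id,
                "start": f.hit.start,
                "end": f.hit.end,
                "patch": f.hit.patch,
                "pct_correlation": f.hit.percent_correlation,
                "patch_gravy": display_value(f.hit.patch_gravy),
            }
            for f in self.families
        ]
        return pd.DataFrame(rows)

    def variants_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parent_id": v.parent_id,
                "mutations": v.mutation_codes,
                "wild_patch": v.wild_patch,
                "mutant_patch": v.mutant_patch,
                "patch_gravy": display_value(v.patch_gravy),
                "delta_gravy": display_delta(v.wild_patch, v.mutant_patch),
            }
            for f in self.families
            for v in f.variants
        ]
        return pd.DataFrame(rows)

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.families:
            for codes, prof in f.mutant_profiles.items():
                for i, (w, m) in enumerate(zip(f.wild_profile.values, prof.values), 1):
                    rows.append(
                        {
                            "protein_id": f.record.id,
                            "mutations": codes,
                            "position": i,
                            "wild_value": round(float(w), 4),
                            "mutant_value": round(float(m), 4),
                            "delta": round(float(m - w), 4),
                        }
                    )
        return pd.DataFrame(rows)

    def candidates_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": c.variant.parent_id,
                "rank": c.rank,
                "mutations": c.mutation_codes,
                "mutant_patch": c.variant.mutant_patch,
                "patch_gravy": display_value(c.variant.patch_gravy),
                "delta_gravy": display_delta(c.variant.wild_patch, c.variant.mutant_patch),
                "pct_correlation": c.percent_correlation,
                "agg_max_gain": round(c.agg_delta.max_gain, 4),
                "n_new_peaks": c.agg_delta.n_new,
                "n_increased_peaks": c.agg_delta.n_increased,
                "reference_gravy": display_value(c.reference_gravy),
                "passes_gravy_filter": c.passes_gravy_filter,
            }
            for f in self.families
            for c in f.candidates
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "seed": self.config.seed,
            "motif": self.config.motif,
            "n_proteins": len(self.families),
            "families": [
                {
                    "protein_id": f.record.id,
                    "patch_start": f.patch_start,
                    "patch": f.patch,
                    "pct_correlation": f.hit.percent_correlation,
                    "wild_patch_gravy": display_value(gravy(f.patch).gravy),
                    "n_variants": len(f.variants),
                    "n_candidates": len(f.candidates),
                    "top_candidate": f.candidates[0].mutation_codes if f.candidates else None,
                    "top_candidate_gravy": (
                        display_value(f.candidates[0].variant.patch_gravy)
                        if f.candidates
                        else None
                    ),
                }
                for f in self.families
            ],
        }

    def write(self, outdir: str | Path) -> None:
        """Write hits/variants/profiles/candidates TSVs and a JSON summary."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.hits_frame().to_csv(out / "hits.tsv", sep="\t", index=False)
        self.variants_frame().to_csv(out / "variants.tsv", sep="\t", index=False)
        self.profiles_frame().to_csv(out / "profiles.tsv", sep="\t", index=False)
        with open(out / "candidates.tsv", "w") as fh:
            fh.write(REPORT_HEADER)
            self.candidates_frame().to_csv(fh, sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


class PipelineStageError(GroelDesignError):
    """An error raised by a pipeline stage, annotated with stage and record."""


def _stage(name: str, record_id: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(
                    f"stage {name!r} failed on record {record_id!r}: {exc}"
                ) from exc
            return False

    return _Ctx()


def run_pipeline(
    records: Sequence[ProteinRecord] | str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run scan → patch extension → mutagenesis → GRAVY → aggregation → ranking.

    *records* may be a FASTA path or an already-loaded record sequence.
    If ``config.outdir`` is set the TSV/JSON report bundle is written there.
    """
    if isinstance(records, (str, Path)):
        records = read_fasta(records)
    result = PipelineResult(config=config)
    for record in records:
        rid = record.id
        with _stage("scan", rid):
            hits = scan_motif(
                record, config.motif, config.min_len, config.max_len, config.top_k
            )
            if not hits:
                raise ParameterError("no patch hits found")
            hit = hits[0]
        with _stage("patch-extension", rid):
            patch_start, patch = suggest_patch(record, hit, config.patch_len)
        with _stage("mutagenesis", rid):
            positions = select_mutable_positions(patch, k=2)
            variants = enumerate_double_mutants(
                patch,
                positions,
                alphabet=config.alphabet,
                parent_id=rid,
                patch_start=patch_start,
            )
        with _stage("aggregation", rid):
            prof_kwargs = dict(
                window=config.window,
                threshold=config.threshold,
                min_run=config.min_run,
                weights=config.weights,
            )
            wild_profile = aggregation_profile(record, **prof_kwargs)
            mutant_profiles: dict[str, AggregationProfile] = {}
            deltas: dict[str, PeakDelta] = {}
            for v in variants:
                mutant_record, codes = lift_to_protein(v, record)
                mp = aggregation_profile(mutant_record, **prof_kwargs)
                mutant_profiles[codes] = mp
                deltas[codes] = compare_profiles(wild_profile, mp)
        with _stage("ranking", rid):
            kept = gravy_filter(variants, config.motif, config.tolerance)
            candidates = rank_candidates(
                kept, deltas, hit.percent_correlation, config.motif
            )
        family = FamilyResult(
            record=record,
            hit=hit,
            patch_start=patch_start,
            patch=patch,
            variants=variants,
            wild_profile=wild_profile,
            mutant_profiles=mutant_profiles,
            deltas=deltas,
            candidates=candidates,
        )
        result.families.append(family)
        logger.info(
            "%s: patch %s at %d (%.1f%%), %d variants, %d candidates, top %s",
            rid, patch, patch_start, hit.percent_correlation,
            len(variants), len(candidates),
            candidates[0].mutation_codes if candidates else "-",
        )
    if config.outdir is not None:
        result.write(config.outdir)
    return result
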
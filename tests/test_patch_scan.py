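import pytest
from Bio import Align
from hypothesis import given
from hypothesis import strategies as st

from groeldesign import (
    FixtureSpec,
    ProteinRecord,
    local_align,
    scan_motif,
    suggest_patch,
    synth_protein,
    ungapped_identity,
)
from groeldesign.errors import ParameterError

from conftest import AMINO_ACIDS, KD_ORACLE

MOTIF = "GGIVLTG"
peptides = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=12)


def oracle_best_identity(query, motif):
    """Independent slide-and-count: best identity of shorter along longer."""
    short, long_ = (query, motif) if len(query) <= len(motif) else (motif, query)
    best = []
    for off in range(len(long_) - len(short) + 1):
        n = sum(1 for i, aa in enumerate(short) if aa == long_[off + i])
        best.append(n)
    return max(best)


def oracle_scan(record, motif, min_len, max_len, top_k):
    """Brute-force enumeration + sort, sharing no code with the scanner."""
    seq = record.sequence
    hits = []
    for length in range(min_len, min(max_len, len(seq)) + 1):
        for s in range(len(seq) - length + 1):
            window = seq[s : s + length]
            n = oracle_best_identity(window, motif)
            pct = round(100.0 * n / min(length, len(motif)), 1)
            g = round(sum(KD_ORACLE[aa] for aa in window) / length, 9)
            hits.append((s + 1, s + length, window, pct, n, g))
    hits.sort(key=lambda h: (-h[3], -h[5], h[0], h[1]))
    return hits[:top_k]


class TestUngappedIdentity:
    @pytest.mark.parametrize(
        "query,n_expected,pct_expected",
        [
            ("GKLFSTG", 3, 42.9),  # 3/7 position-wise identities
            ("GDVIET", 2, 33.3),  # best offset over the 7-mer motif, 2/6
            ("GGIVLTG", 7, 100.0),
        ],
    )
    def test_published_percent_correlations(self, query, n_expected, pct_expected):
        _, n, pct = ungapped_identity(query, MOTIF)
        assert n == n_expected
        assert round(pct, 1) == pct_expected

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            ungapped_identity("", MOTIF)

    @given(a=peptides, b=peptides)
    def test_symmetry_and_oracle_agreement(self, a, b):
        _, n_ab, pct_ab = ungapped_identity(a, b)
        _, n_ba, pct_ba = ungapped_identity(b, a)
        assert (n_ab, pct_ab) == (n_ba, pct_ba)
        assert n_ab == oracle_best_identity(a, b)

    @given(a=peptides, b=peptides)
    def test_percent_invariant_under_joint_reversal(self, a, b):
        assert ungapped_identity(a, b)[2] == pytest.approx(
            ungapped_identity(a[::-1], b[::-1])[2]
        )


class TestScanMotif:
    def test_motif_as_whole_sequence_is_perfect_hit(self):
        hits = scan_motif(ProteinRecord("m", MOTIF), MOTIF, min_len=7, max_len=7)
        assert hits[0].percent_correlation == 100.0
        assert (hits[0].start, hits[0].end) == (1, 7)

    def test_disjoint_alphabet_scores_zero(self):
        hits = scan_motif(ProteinRecord("a", "A" * 30), MOTIF)
        assert hits[0].n_identities == 0
        assert hits[0].percent_correlation == 0.0

    def test_sequence_shorter_than_min_len_yields_empty(self):
        assert scan_motif(ProteinRecord("s", "GGI"), MOTIF, min_len=6) == []

    def test_embedded_hcha_patch_is_top_hit(self):
        rec = synth_protein(
            FixtureSpec(seed=7, length=100, embedded_patch="GKLFSTG", patch_start=40)
        )
        top = scan_motif(rec, MOTIF)[0]
        assert top.percent_correlation == 42.9
        # the hit covers the embedded patch
        assert top.start <= 40 and top.end >= 40 + 6 or top.patch in rec.sequence

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rec = synth_protein(
            FixtureSpec(seed=seed, length=90, embedded_patch="GDVIETQ", patch_start=16)
        )
        got = scan_motif(rec, MOTIF, min_len=6, max_len=8, top_k=5)
        expected = oracle_scan(rec, MOTIF, 6, 8, 5)
        assert [(h.start, h.end, h.patch, h.percent_correlation, h.n_identities)
                for h in got] == [e[:5] for e in expected]

    def test_rank_never_drops_when_identities_increase(self):
        rec = synth_protein(
            FixtureSpec(seed=3, length=80, embedded_patch="GDVIETQ", patch_start=30)
        )
        before = {(h.start, h.end): i for i, h in enumerate(scan_motif(rec, MOTIF, top_k=10**6))}
        # edit the patch window to raise its identity to the motif
        seq = rec.sequence[:29] + "GGVIETQ" + rec.sequence[36:]
        edited = ProteinRecord(rec.id, seq)
        after = {(h.start, h.end): i for i, h in enumerate(scan_motif(edited, MOTIF, top_k=10**6))}
        assert after[(30, 36)] <= before[(30, 36)]

    def test_invalid_window_bounds(self):
        with pytest.raises(ParameterError):
            scan_motif(ProteinRecord("m", MOTIF), MOTIF, min_len=3, max_len=20)


class TestSuggestPatch:
    def test_six_mer_hit_extends_rightward(self):
        rec = ProteinRecord("r", "EEEEEGDVIETQEEEE")
        hits = scan_motif(rec, MOTIF, min_len=6, max_len=6, top_k=1)
        start, patch = suggest_patch(rec, hits[0])
        assert (start, patch) == (6, "GDVIETQ")

    def test_extension_falls_back_leftward_at_sequence_end(self):
        rec = ProteinRecord("r", "EEEEGDVIET")
        hits = scan_motif(rec, MOTIF, min_len=6, max_len=6, top_k=1)
        assert hits[0].start == 5
        start, patch = suggest_patch(rec, hits[0])
        assert (start, patch) == (4, "EGDVIET")


class TestLocalAlign:
    def test_self_alignment_score(self):
        aln = local_align(MOTIF, MOTIF, match=2, mismatch=-1, gap=-2)
        assert aln.score == 14  # 2 x 7 matched columns
        assert aln.percent_identity == 100.0

    def test_single_residue_match(self):
        assert local_align("I", "I", match=2, mismatch=-1, gap=-2).score == 2

    def test_divergent_patch_best_local_block(self):
        # best local alignment of GKLFSTG vs the motif is the shared TG
        # suffix block: score 4, two perfectly matched columns (the three
        # ungapped-scan identities are interrupted by mismatch penalties)
        aln = local_align("GKLFSTG", MOTIF, match=2, mismatch=-1, gap=-2)
        assert aln.score == 4
        assert (aln.aligned_query, aln.aligned_motif) == ("TG", "TG")
        assert aln.percent_identity == 100.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            local_align("GG", "GG", match=-1, mismatch=-1, gap=-2)
        with pytest.raises(ParameterError):
            local_align("GG", "GG", match=2, mismatch=1, gap=-2)

    @given(a=peptides, b=peptides)
    def test_score_matches_biopython_aligner(self, a, b):
        """Independent cross-check of the Smith-Waterman score."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        expected = aligner.score(a, b)
        got = local_align(a, b, match=2, mismatch=-1, gap=-2).score
        assert got == pytest.approx(max(expected, 0.0))
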
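# Methods

## The design problem

GroEL recognizes substrates through exposed hydrophobic patches; the GroES
mobile loop's GGIVLTG segment is the canonical example of a patch with the
right character (GRAVY 1.514). The package turns a protein that lacks such a
patch into candidate substrates by finding its most mobile-loop-like window
and making it hydrophobic with exactly two substitutions, then checking that
the edit raises local aggregation propensity (a proxy for GroEL
recognisability) rather than merely raising mean hydropathy.

## Patch discovery

Every window of length 6–8 (the motif length ± 1) is scored against the
motif by **ungapped position-wise identity**: the shorter peptide slides
along the longer at every full-overlap offset and the best count is kept.
Percent correlation uses the shorter length as denominator, which is what
makes a 6-mer window able to out-score a 7-mer containing it (2/6 = 33.3% >
2/7). Hits are ordered by percent correlation, then patch GRAVY (more
hydrophobic preferred), then position; the GRAVY tie-break key is quantized
to 9 decimals so floating-point summation order cannot flip ties. A
Smith–Waterman local aligner (linear gap penalty, deterministic traceback
preferring diagonal, then up, then left) is available as a cross-check, but
the identity scan is the production scorer: it is the arithmetic that
reproduces the published percent-correlation values, whereas gapped local
alignment optimizes a different objective (for GKLFSTG vs GGIVLTG its
optimum is the two-column TG block, not the three scattered identities).

The best hit is extended to a fixed 7-residue mutation patch anchored at the
hit start, growing rightward and falling back leftward at the sequence end.
This reconstruction covers the published behaviour (the 6-mer GDVIET is
reported together with the 7-mer suggestion GDVIETQ) but is a convention,
not a law of the motif.

## Site selection and mutagenesis

The two mutated sites are the patch's two lowest Kyte–Doolittle positions,
ties to the left. We use hydropathy rather than formal charge because the
operational record includes an uncharged serine among the mutated sites:
"lowest hydropathy" selects D/E in GDVIETQ and K/S in GKLFSTG (S = −0.8
undercuts T = −0.7), whereas "charged only" cannot. An explicit
`--positions` override exists for users who disagree on a given patch.

All 3² ordered substitutions over {I, L, V} are generated, first site
cycling slowest, alphabet in I, L, V order, so the nine variants appear in a
stable, diffable order. Single mutants are skipped by default: one
substitution changes a 7-mer's GRAVY by at most (4.5 − (−4.5))/7 ≈ 1.3 and
in practice far less, too little to lift a charged patch to the mobile-loop
level. If a selected site's wild residue is already in the substitution
alphabet the enumeration refuses: the library could then contain variants
with fewer than two real changes (or the wild type itself), breaking the
"nine distinct double mutants" contract. The default selection rule can
never trigger this, since I/L/V sit at the top of the scale.

## GRAVY and display conventions

GRAVY is the arithmetic mean of Kyte–Doolittle indices (math.fsum for exact
summation). Internally everything is full precision. **Displayed** values
are truncated toward zero at three decimals (1.92857 → 1.928), matching the
convention of the reference tables reproduced by the test suite, and the
reported ΔGRAVY column is the difference of the two displayed GRAVYs rather
than the truncated full-precision difference — the two disagree by one unit
in the last place exactly when the true difference lands on a thousandth
boundary (e.g. 15.4/7 = 2.200 displays as 2.199). `delta_gravy()` returns
full precision; `display_delta()` implements the report convention.

## Aggregation-propensity surrogate

Full statistical-mechanics aggregation predictors need parameters that are
not public in a reusable form, so the package defines its own transparent
score with a deliberately modest contract. Per residue:

    raw(aa) = clamp01( 0.5·h(aa) + 0.4·b(aa) − 0.1·|q(aa)| )

* `h`: Kyte–Doolittle hydropathy min–max-normalized to [0, 1];
* `b`: Chou–Fasman β-sheet propensity P(β), min–max-normalized (Glu 37 →
  0, Val 170 → 1);
* `|q|`: 1 for D/E/K/R, 0.5 for H, 0 otherwise;
* P and G are forced to 0 as β-breakers.

The profile is 100 × the mean raw score over a centered window of 5
(truncated at the ends), and peaks are maximal runs of > 20 (on the 0–100
scale) lasting ≥ 5 residues — the usual minimum length for an
aggregation-nucleating segment. Weights and thresholds are defaults exposed
in `PipelineConfig`; no test or ranking depends on their exact values, only
on ordering and monotonicity: because the window mean is monotone in its
inputs, replacing a residue by one of higher raw score can only raise the
profile, so hydrophobic double mutations in the patch are guaranteed to
create or heighten a peak there. Window means are computed with per-window
local sums (not a running prefix sum) so that positions whose windows
exclude every edited site are bit-identical between wild type and mutant.

What the surrogate does **not** claim: numeric agreement with any published
aggregation predictor, pH/temperature dependence, or helix/turn channels.
Its outputs are comparative (mutant vs wild of the same protein), not
absolute propensities.

## Filtering and ranking

Variants pass when patch GRAVY ≥ GRAVY(GGIVLTG) − tolerance (tolerance 0 by
default; the flag operationalizes "comparable" since no margin is defined
anywhere). Ranking is lexicographic: patch GRAVY descending, then maximum
profile gain descending, then mutation-code string ascending for
determinism. Force-field energy estimation is out of scope, so stability
does not enter the key; the candidates report states this in its header.
For both reference families the GRAVY maximum is unique, so the ranking
reproduces the canonical picks (D17I E20I and K63I S66I) regardless.

## Synthetic fixtures

Fixtures embed a chosen patch at an exact 1-based position in a background
drawn uniformly from the low-hydropathy alphabet {A, S, T, N, Q, D, E, K,
R}, via `numpy.random.default_rng` (PCG64) with an explicit seed — one
documented generator, platform-independent. The anchored fixtures place
GDVIETQ at 16–22 and GKLFSTG at 62–68 so that absolute mutation codes match
the conventional residue numbering of the two reference proteins. Decoy
windows with a controlled fraction of identities to the patch can be added
to stress the scanner's ranking.

What the fixtures do not emulate: real amino-acid composition statistics,
domain structure, or the possibility of several genuine hydrophobic patches
per protein. Consequently, passing tests show the pipeline's arithmetic and
ordering are correct and seed-stable, not that the scan would pick the same
patch in a real proteome background. One real-data effect the background
*does* exercise: an alanine adjacent to the embedded patch can tie or
out-rank the canonical window (same identity count, higher GRAVY), shifting
the suggested 7-mer frame by one. The lowest-hydropathy site selection still
lands on the same absolute residues in every such frame, which is why the
end-to-end checks assert mutation codes rather than window coordinates.

## Numerical choices and degenerate inputs

* Truncated (shrinking) windows at sequence edges, for both hydropathy and
  aggregation profiles: keeps track length equal to sequence length without
  inventing a padding value.
* Percentages display at one decimal, half-up; GRAVYs display truncated at
  three decimals (see above).
* Scan ties: percent, then quantized GRAVY, then leftmost start, then
  shortest window.
* Sequences shorter than the minimum window yield an empty hit list with a
  logged warning (not an error); an empty peptide, an even profile window,
  or a non-canonical residue (B, J, O, U, X, Z) are hard errors — every
  downstream score needs a defined hydropathy value, so nothing is silently
  remapped.
* Mutation codes are validated against the sequence (wild residue must
  match; silent substitutions like D17D are rejected at parse time).

## Problem sizes

Tests and the acceptance script run on 90–120-residue synthetic proteins,
the natural scale for this design loop (patches are 6–8 residues; the two
reference proteins are a few hundred residues). The scan is O(n·L·m) for n
residues, L window lengths and motif length m; whole-proteome screens would
batch `run_pipeline` over records.
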
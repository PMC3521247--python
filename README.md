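# groeldesign

In-silico engineering of non-substrate proteins into candidate substrates for
the *E. coli* chaperonin GroEL.

GroEL binds non-native polypeptides through hydrophobic contacts in its
central cavity; its co-chaperonin GroES docks via the mobile-loop segment
whose core patch is the heptapeptide **GGIVLTG**. A protein that lacks such a
mobile-loop-like hydrophobic patch is a poor GroEL substrate even when it is
aggregation-prone. `groeldesign` automates the design loop that fixes this:

1. **Scan** a protein for short windows (6–8 residues) most similar to
   GGIVLTG, scored by ungapped position-wise identity
   (percent correlation = 100 × identities / window length).
2. **Extend** the best hit to a 7-residue patch and pick its two
   least-hydrophobic positions (lowest Kyte–Doolittle values).
3. **Mutate**: enumerate all 3² = 9 double substitutions of those positions
   over the hydrophobic alphabet {I, L, V}.
4. **Score** each variant by patch GRAVY (grand average of hydropathicity,
   GRAVY = Σᵢ KD(aaᵢ)/n on the Kyte–Doolittle scale, −4.5 for Arg to +4.5 for
   Ile) and by a windowed per-residue β-aggregation-propensity profile on a
   0–100 scale, comparing mutant vs wild type for new or heightened peaks.
5. **Rank**: keep variants whose patch GRAVY is at least that of GGIVLTG
   (1.514) and order by GRAVY, then aggregation gain.

It is aimed at protein engineers and chaperone biologists who want a
reproducible, scriptable version of this workflow instead of a chain of web
tools. Sequence I/O is FASTA; mutations use one-letter codes (`D17I`).

## Worked example

The repository ships no real sequences; seeded synthetic fixtures embed the
two classic design targets — a ureidoglycolate-hydrolase-like protein with
patch GDVIETQ at residues 16–22, and an Hsp31-like protein with GKLFSTG at
62–68 — in a low-hydropathy random background:

```bash
groeldesign fixtures --seed 11 --out fixtures.fa
groeldesign pipeline --fasta fixtures.fa --outdir run --seed 11
```

prints

```
ALLA_like_synthetic: patch GDVIETQ at 16 (33.3%), top candidate D17I E20I (GRAVY 1.871)
HCHA_like_synthetic: patch GKLFSTG at 62 (42.9%), top candidate K63I S66I (GRAVY 2.014)
reports written to run
```

So the scan recovered each embedded patch (GDVIET matches GGIVLTG at 2/6
positions = 33.3%, GKLFSTG at 3/7 = 42.9%); the two lowest-hydropathy sites
are D17/E20 and K63/S66; and the double-isoleucine mutants rank first — the
wild GDVIETQ patch at GRAVY −0.414 becomes GIVIITQ at 1.871, and GKLFSTG at
0.057 becomes GILFITG at 2.014, both above the GGIVLTG reference of 1.514.
`run/candidates.tsv` holds the full ranking:

```
protein_id           rank  mutations  mutant_patch  patch_gravy  delta_gravy  pct_correlation  agg_max_gain
ALLA_like_synthetic  1     D17I E20I  GIVIITQ       1.871        2.285        33.3             34.6633
ALLA_like_synthetic  2     D17I E20V  GIVIVTQ       1.828        2.242        33.3             34.9315
ALLA_like_synthetic  3     D17V E20I  GVVIITQ       1.828        2.242        33.3             34.9315
...
```

`agg_max_gain` is the largest per-residue increase of the 0–100 aggregation
profile; every mutant raises an aggregation peak over the mutated patch, as
expected when two charged/polar residues become hydrophobic. The same stages
are available individually (`scan`, `mutate`, `profile`) and as library
functions (`scan_motif`, `enumerate_double_mutants`, `aggregation_profile`,
`run_pipeline`).

Reported GRAVY values are truncated to three decimals and the `delta_gravy`
column is the difference of the displayed values — the conventions of the
reference tables this package reproduces; full precision is kept internally.

## Limitations

Aggregation propensity is a transparent hydropathy/β-propensity surrogate
(documented in `docs/methods.md`), not a statistical-mechanics predictor;
molecular-dynamics stability estimation is out of scope. Designs are
hypotheses for experimental testing, not guarantees of GroEL binding.
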
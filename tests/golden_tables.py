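"""Published patch values the package must reproduce to three decimals.

The enumeration order is the canonical report order: first mutated position
cycling slowest, substitution alphabet in I, L, V order.
"""

# (mutant patch, patch GRAVY) for the ureidoglycolate-hydrolase family,
# wild patch GDVIETQ (positions 16-22, mutated sites D17/E20).
ALLA_MUTANTS = [
    ("GIVIITQ", 1.871),
    ("GIVILTQ", 1.771),
    ("GIVIVTQ", 1.828),
    ("GLVIITQ", 1.771),
    ("GLVILTQ", 1.671),
    ("GLVIVTQ", 1.728),
    ("GVVIITQ", 1.828),
    ("GVVILTQ", 1.728),
    ("GVVIVTQ", 1.785),
]

# Same for the Hsp31 family, wild patch GKLFSTG (62-68, sites K63/S66).
HCHA_MUTANTS = [
    ("GILFITG", 2.014),
    ("GILFLTG", 1.914),
    ("GILFVTG", 1.971),
    ("GLLFITG", 1.914),
    ("GLLFLTG", 1.814),
    ("GLLFVTG", 1.871),
    ("GVLFITG", 1.971),
    ("GVLFLTG", 1.871),
    ("GVLFVTG", 1.928),
]

ALLA_WILD_PATCH = "GDVIETQ"
ALLA_WILD_GRAVY = -0.414
HCHA_WILD_PATCH = "GKLFSTG"
HCHA_WILD_GRAVY = 0.057

# "Increase in GRAVY value" columns, same enumeration order.
ALLA_DELTAS = [2.285, 2.185, 2.242, 2.185, 2.085, 2.142, 2.242, 2.142, 2.199]
HCHA_DELTAS = [1.957, 1.857, 1.914, 1.857, 1.757, 1.814, 1.914, 1.814, 1.871]

MOTIF = "GGIVLTG"
MOTIF_GRAVY = 1.514
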
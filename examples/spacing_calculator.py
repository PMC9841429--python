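"""Aligned spacing (D_toStart) of candidate start codons in designed RBS windows.

Builds small mRNA windows — an SD motif followed by a non-pairing spacer —
and computes where each start codon of an AUGUG/GUGUG overlap sits relative
to the 16S rRNA 3' end. D_toStart ~13-14 is the experimentally optimal
position; the pentamer's two codons always sit 2 nt apart.
"""

from ambistart import compute_d_to_start, find_sd_matches

CASES = [
    ("strong SD, short spacer", "CC" + "UAAGGAGG" + "CC", (0, 2)),
    ("hdhA-style AUGUG RBS", "CC" + "AGGAGGU" + "CC", (0, 2)),
    ("pqiA-style AUGUG RBS", "CC" + "UAAGGAG" + "CCCCC", (0, 2)),
    ("narQ-style GUGUG RBS", "CC" + "GGAG" + "CCCCCCC", (0, 2)),
]

for label, window, offsets in CASES:
    (match,) = find_sd_matches(window)
    ds = [compute_d_to_start(match, off).d_to_start for off in offsets]
    print(
        f"{label:26s} SD {match.motif:9s} pairs aSD p{match.asd_start}..p{match.asd_end}"
        f"  ->  D_toStart {ds[0]}/{ds[1]} (5'/3' codon)"
    )

print()
print("A 5' codon near D 13-14 favors the 5' start; D <= 11 pins the 3' start;")
print("D 12 (AUGUG) or 12-16 (GUGUG) lands in the ambiguous window.")
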
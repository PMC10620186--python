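"""Pick semi-degenerate codons for favored residue sets.

For each set the full co-optimal tier of stop-free IUPAC triplets is
shown; every tier member encodes exactly the requested residues (an
exact cover), found by exhaustive search over all 15^3 = 3375 triplets.
"""

from heliscreen import best_degenerate_codon

for aas in [{"F", "L", "I", "M"}, {"Y", "F"}, {"V", "I"}, {"D", "E"}]:
    tier = best_degenerate_codon(aas)
    label = "/".join(sorted(aas))
    print(f"{label:12s} -> " + ", ".join(
        f"{dc.triplet} ({'+'.join(dc.codons)})" for dc in tier
    ))
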
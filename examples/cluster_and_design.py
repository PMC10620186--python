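"""From hit peptides to a focused-library primer.

Builds two synthetic sequence families, clusters them, classifies each
logo position (fixed / partial / free), converts one family into a 20-mer
focused design with semi-degenerate codons, and assembles the primer.
"""

import numpy as np

from heliscreen import (
    assemble_primer,
    build_logo,
    classify_positions,
    cluster_peptides,
    design_from_logo,
    diversity,
    naive_design,
)
from heliscreen.genetics import RANDOM_ALPHABET

rng = np.random.default_rng(7)
design14 = naive_design()  # Cys staple at 4/11, scaffold Ala at 7/8

# two families: shared binding cores, randomized elsewhere
def family(core: dict[int, str], n: int = 12) -> list[str]:
    peps = []
    for _ in range(n):
        pep = [
            core.get(p.index) or (p.aas if p.kind == "fixed" else rng.choice(list(RANDOM_ALPHABET)))
            for p in design14.positions
        ]
        peps.append("".join(pep))
    return peps

peps = family({1: "W", 2: "E", 5: "F"}) + family({1: "H", 2: "S", 5: "T", 12: "D"})
clusters = cluster_peptides(peps, cut_height=0.55)
print(f"{len(clusters)} families from {len(peps)} hit peptides")

logo = build_logo(clusters[0])
classes = classify_positions(logo, forced_fixed={4: "C", 11: "C", 7: "A", 8: "A"})
print(
    "position classes:",
    " ".join(f"{i}:{c.kind}{':' + c.aas if c.aas else ''}" for i, c in enumerate(classes, 1)),
)

spec20 = design_from_logo(logo, target_length=20)
primer = assemble_primer(spec20)
report = diversity(spec20)
print("focused 20-mer primer (coding strand):")
print(primer.coding)
print(f"theoretical peptide diversity: {report.theoretical_diversity:.3g}")
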
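"""Genetic-code and IUPAC helpers shared across the package.

The library chemistry uses trimer-phosphoramidite synthesis, so randomized
positions draw whole codons from a 16-residue alphabet that excludes
cysteine, lysine, proline and glycine (staple integrity, chemistry and
helicity constraints).
"""

from __future__ import annotations

import itertools

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: residues excluded from randomized (trimer-mix) positions
FORBIDDEN_RANDOM: frozenset[str] = frozenset("CKPG")

#: the 16-letter alphabet available at a fully randomized position
RANDOM_ALPHABET: str = "".join(a for a in AMINO_ACIDS if a not in FORBIDDEN_RANDOM)

STANDARD_CODE: dict[str, str] = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_bases, _bases, _bases)):
    STANDARD_CODE[_b1 + _b2 + _b3] = _aas[_i]

#: one defined codon per amino acid, used when reverse-encoding peptides.
#: W/E/C/A match the codons used in the worked focused-library primer
#: (TGG/GAA/TGT/GCA); the rest are common E. coli codons.
DEFAULT_CODON_TABLE: dict[str, str] = {
    "A": "GCA", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAT",
}

IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(dna: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate DNA with the standard code; stop codons become ``*``.

    Raises ``ValueError`` on a length not divisible by 3 or on any base
    outside A/C/G/T (ambiguity codes are not translated).
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    dna = dna.upper()
    aas = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        try:
            aas.append(STANDARD_CODE[codon])
        except KeyError:
            raise ValueError(f"cannot translate codon {codon!r} at position {i}") from None
    return "".join(aas)


def expand_iupac_triplet(triplet: str) -> list[str]:
    """All defined codons matching a three-letter IUPAC triplet, sorted."""
    if len(triplet) != 3:
        raise ValueError(f"codon spec must have 3 letters, got {triplet!r}")
    try:
        sets = [IUPAC_DNA[c] for c in triplet.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in {triplet!r}") from exc
    return sorted("".join(p) for p in itertools.product(*sets))
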
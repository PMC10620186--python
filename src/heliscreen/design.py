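"""Library design specifications.

A phage-display Helicon library is defined position by position: fixed
residues (including the two stapling cysteines and two scaffolding
alanines), partially randomized positions restricted to a small favored
set via a semi-degenerate codon, and fully randomized positions built from
trimer phosphoramidites over the 16-residue alphabet (no C/K/P/G). The
insert is cloned between constant flanks carrying KpnI (coding strand) and
EagI (antisense) restriction sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .genetics import (
    DEFAULT_CODON_TABLE,
    FORBIDDEN_RANDOM,
    RANDOM_ALPHABET,
    expand_iupac_triplet,
    translate,
)

KPNI_MOTIF = "GGTACC"
EAGI_MOTIF = "CGGCCG"

#: constant flanks of the worked focused-library primer (coding strand);
#: the 5' flank carries the KpnI site
DEFAULT_FLANK5 = "CATGCCCGGGTACCTTTCTATTCTCACTCTGCGCCG"
DEFAULT_FLANK3 = "GGTGGTTCTGGCGCAGGTCGTGGTTC"

Kind = Literal["fixed", "choice", "trimer_random"]


@dataclass(frozen=True)
class PositionSpec:
    """One peptide position of a library design.

    ``index`` is 1-based. ``kind`` is ``fixed`` (one residue, defined
    codon), ``choice`` (2-5 favored residues, IUPAC degenerate codon) or
    ``trimer_random`` (any of the 16 allowed residues; codon spec ``X``,
    one trimer-phosphoramidite incorporation).
    """

    index: int
    kind: Kind
    aas: str
    codon_spec: str

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if len(self.aas) != 1:
                raise ValueError(f"fixed position {self.index} needs exactly one residue")
            if translate(self.codon_spec) != self.aas:
                raise ValueError(
                    f"position {self.index}: codon {self.codon_spec} does not encode {self.aas}"
                )
        elif self.kind == "choice":
            if not 2 <= len(self.aas) <= 5:
                raise ValueError(
                    f"choice position {self.index} needs 2-5 residues, got {len(self.aas)}"
                )
            if self.codon_spec != "X":
                encoded = {translate(c) for c in expand_iupac_triplet(self.codon_spec)}
                if not set(self.aas) <= encoded:
                    raise ValueError(
                        f"position {self.index}: codon {self.codon_spec} misses residues "
                        f"{set(self.aas) - encoded}"
                    )
        elif self.kind == "trimer_random":
            if set(self.aas) != set(RANDOM_ALPHABET):
                raise ValueError(
                    f"trimer-randomized position {self.index} must use the 16-residue alphabet"
                )
            if self.codon_spec != "X":
                raise ValueError(f"trimer-randomized position {self.index} uses codon spec 'X'")
        else:
            raise ValueError(f"unknown position kind {self.kind!r}")

    @property
    def allowed(self) -> str:
        return self.aas


def fixed(index: int, aa: str, codon_table: dict[str, str] | None = None) -> PositionSpec:
    table = codon_table or DEFAULT_CODON_TABLE
    return PositionSpec(index, "fixed", aa, table[aa])


def choice(index: int, aas: str, codon_spec: str) -> PositionSpec:
    return PositionSpec(index, "choice", "".join(sorted(set(aas))), codon_spec)


def trimer_random(index: int) -> PositionSpec:
    return PositionSpec(index, "trimer_random", RANDOM_ALPHABET, "X")


@dataclass
class LibraryDesignSpec:
    """Per-position design of a Helicon phage library insert."""

    length: int
    positions: list[PositionSpec]
    flank5_dna: str = DEFAULT_FLANK5
    flank3_dna: str = DEFAULT_FLANK3
    fixed_codon_table: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CODON_TABLE))
    restriction_sites: dict[str, str] = field(
        default_factory=lambda: {"KpnI": KPNI_MOTIF, "EagI": EAGI_MOTIF}
    )
    staple_positions: tuple[int, int] | None = None
    scaffold_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.positions) != self.length:
            raise ValueError(
                f"{len(self.positions)} position specs for declared length {self.length}"
            )
        for i, pos in enumerate(self.positions, start=1):
            if pos.index != i:
                raise ValueError(f"position specs out of order at index {i}")
        cys = tuple(p.index for p in self.positions if p.kind == "fixed" and p.aas == "C")
        if len(cys) != 2:
            raise ValueError(f"design must fix exactly two stapling cysteines, found {cys}")
        if self.staple_positions is None:
            self.staple_positions = cys
        elif tuple(self.staple_positions) != cys:
            raise ValueError("declared staple positions disagree with fixed cysteines")
        for i in self.scaffold_positions:
            p = self.positions[i - 1]
            if not (p.kind == "fixed" and p.aas == "A"):
                raise ValueError(f"scaffold position {i} is not a fixed alanine")
        if KPNI_MOTIF not in self.flank5_dna:
            raise ValueError("5' flank lacks the KpnI motif")

    # -- membership -------------------------------------------------------

    def matches(self, peptide: str) -> bool:
        """True iff the peptide is a possible member of this library."""
        if len(peptide) != self.length or "*" in peptide:
            return False
        return all(aa in pos.allowed for aa, pos in zip(peptide, self.positions))

    # -- sampling / encoding ----------------------------------------------

    def sample_peptides(self, n: int, rng: np.random.Generator) -> list[str]:
        """Draw n random members (uniform per position)."""
        cols = []
        for pos in self.positions:
            alphabet = np.array(list(pos.allowed))
            cols.append(alphabet[rng.integers(0, len(alphabet), size=n)])
        return ["".join(row) for row in zip(*cols)]

    def encode_peptide(self, peptide: str) -> str:
        """Reverse-encode a member peptide into insert DNA.

        Deterministic: fixed positions use their defined codon; degenerate
        positions use the lexicographically first matching expansion codon;
        trimer positions use the package codon table.
        """
        if not self.matches(peptide):
            raise ValueError(f"peptide {peptide!r} is not a member of this design")
        codons = []
        for aa, pos in zip(peptide, self.positions):
            if pos.kind == "fixed":
                codons.append(pos.codon_spec)
            elif pos.kind == "choice" and pos.codon_spec != "X":
                matching = [c for c in expand_iupac_triplet(pos.codon_spec) if translate(c) == aa]
                codons.append(matching[0])
            else:
                codons.append(self.fixed_codon_table[aa])
        return "".join(codons)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "positions": [
                {"index": p.index, "kind": p.kind, "aas": p.aas, "codon_spec": p.codon_spec}
                for p in self.positions
            ],
            "flank5_dna": self.flank5_dna,
            "flank3_dna": self.flank3_dna,
            "fixed_codon_table": self.fixed_codon_table,
            "restriction_sites": self.restriction_sites,
            "staple_positions": list(self.staple_positions or ()),
            "scaffold_positions": list(self.scaffold_positions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryDesignSpec":
        return cls(
            length=d["length"],
            positions=[
                PositionSpec(p["index"], p["kind"], p["aas"], p["codon_spec"])
                for p in d["positions"]
            ],
            flank5_dna=d.get("flank5_dna", DEFAULT_FLANK5),
            flank3_dna=d.get("flank3_dna", DEFAULT_FLANK3),
            fixed_codon_table=d.get("fixed_codon_table", dict(DEFAULT_CODON_TABLE)),
            restriction_sites=d.get(
                "restriction_sites", {"KpnI": KPNI_MOTIF, "EagI": EAGI_MOTIF}
            ),
            staple_positions=tuple(d["staple_positions"]) if d.get("staple_positions") else None,
            scaffold_positions=tuple(d.get("scaffold_positions", ())),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LibraryDesignSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def naive_design(
    length: int = 14,
    staple: tuple[int, int] = (4, 11),
    scaffold: tuple[int, ...] = (7, 8),
) -> LibraryDesignSpec:
    """A naive cysteine-stapled library: two fixed Cys (the staple), two
    fixed scaffold Ala, every other position trimer-randomized.

    Default coordinates use the i,i+7 staple spacing of the worked 20-mer
    focused design with adjacent scaffold alanines.
    """
    positions = []
    for i in range(1, length + 1):
        if i in staple:
            positions.append(fixed(i, "C"))
        elif i in scaffold:
            positions.append(fixed(i, "A"))
        else:
            positions.append(trimer_random(i))
    return LibraryDesignSpec(
        length=length,
        positions=positions,
        staple_positions=staple,
        scaffold_positions=scaffold,
    )


def pr21_design() -> LibraryDesignSpec:
    """The worked 20-mer focused design:
    X1-X4, W5 E6 C7, X8, E9 A10 A11, (F/I/L/M)12, X13, C14, X15,
    (F/Y)16 (F/Y)17, X18-X20.
    """
    spec = {5: "W", 6: "E", 7: "C", 9: "E", 10: "A", 11: "A", 14: "C"}
    degenerate = {12: ("FILM", "WTK"), 16: ("FY", "TWT"), 17: ("FY", "TWT")}
    positions = []
    for i in range(1, 21):
        if i in spec:
            positions.append(fixed(i, spec[i]))
        elif i in degenerate:
            aas, codon = degenerate[i]
            positions.append(choice(i, aas, codon))
        else:
            positions.append(trimer_random(i))
    return LibraryDesignSpec(
        length=20,
        positions=positions,
        staple_positions=(7, 14),
        scaffold_positions=(10, 11),
    )


__all__ = [
    "PositionSpec",
    "LibraryDesignSpec",
    "fixed",
    "choice",
    "trimer_random",
    "naive_design",
    "pr21_design",
    "KPNI_MOTIF",
    "EAGI_MOTIF",
    "DEFAULT_FLANK5",
    "DEFAULT_FLANK3",
]
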
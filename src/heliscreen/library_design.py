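"""Focused-library design: degenerate-codon optimization, primer
assembly, and diversity/coverage statistics.

A classified cluster logo is converted into an oligonucleotide primer:
fixed positions get defined codons, partial positions get the best
semi-degenerate IUPAC codon for their favored residue set (e.g. WTK for
F/L/I/M, TWT for Y/F, RTT for V/I), and free positions get an ``X`` — one
trimer-phosphoramidite incorporation drawing uniformly from the 16
allowed residues. The coding strand is flanked by constants carrying the
KpnI site; the antisense stub for Klenow extension carries the EagI site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterLogo, PositionClass, classify_positions
from .design import (
    EAGI_MOTIF,
    KPNI_MOTIF,
    LibraryDesignSpec,
    PositionSpec,
    choice as choice_pos,
    fixed as fixed_pos,
    trimer_random,
)
from .genetics import (
    DEFAULT_CODON_TABLE,
    IUPAC_DNA,
    RANDOM_ALPHABET,
    expand_iupac_triplet,
    reverse_complement,
    translate,
)

__all__ = [
    "DegenerateCodon",
    "PrimerDesign",
    "DiversityReport",
    "expand_degenerate_codon",
    "best_degenerate_codon",
    "design_from_logo",
    "assemble_primer",
    "diversity",
]

#: vector context appended after the 3' flank so the antisense stub
#: carries the EagI site
EAGI_TAIL = "GGCCGAAACATG"


@dataclass(frozen=True)
class DegenerateCodon:
    triplet: str
    codons: tuple[str, ...]
    aa_multiset: tuple[str, ...]  # one aa per codon, same order

    @property
    def aa_set(self) -> frozenset[str]:
        return frozenset(self.aa_multiset)

    @property
    def has_stop(self) -> bool:
        return "*" in self.aa_multiset

    def aa_freqs(self) -> dict[str, float]:
        n = len(self.aa_multiset)
        out: dict[str, float] = {}
        for aa in self.aa_multiset:
            out[aa] = out.get(aa, 0.0) + 1.0 / n
        return out


def expand_degenerate_codon(triplet: str) -> DegenerateCodon:
    """Cartesian expansion of a three-letter IUPAC triplet."""
    codons = tuple(expand_iupac_triplet(triplet))
    return DegenerateCodon(
        triplet=triplet.upper(),
        codons=codons,
        aa_multiset=tuple(translate(c) for c in codons),
    )


def _tvd(freqs: dict[str, float], target: dict[str, float]) -> float:
    keys = set(freqs) | set(target)
    return 0.5 * sum(abs(freqs.get(k, 0.0) - target.get(k, 0.0)) for k in keys)


def best_degenerate_codon(
    target_aas: set[str] | str,
    target_freqs: dict[str, float] | None = None,
) -> list[DegenerateCodon]:
    """Rank all 15^3 IUPAC triplets for a favored residue set.

    Stop-containing candidates are excluded outright (displayed peptides
    must be full length). Ranking: exact covers (aa set == target set)
    first, then fewest missing target residues, fewest off-target
    residues, smallest total-variation distance between the codon-implied
    amino-acid distribution and ``target_freqs`` (uniform over the target
    set if absent), fewest codons, and finally lexicographic triplet. The
    whole co-optimal tier (equal on every key but the triplet) is
    returned; its first element is the selection.
    """
    target = set(target_aas)
    if not 1 <= len(target) <= 5:
        raise ValueError("favored residue set must have 1-5 members")
    if target_freqs is None:
        target_freqs = {aa: 1.0 / len(target) for aa in target}
    else:
        total = sum(target_freqs.get(aa, 0.0) for aa in target)
        target_freqs = {aa: target_freqs.get(aa, 0.0) / total for aa in target}

    scored: list[tuple[tuple, DegenerateCodon]] = []
    for letters in itertools.product(IUPAC_DNA, repeat=3):
        dc = expand_degenerate_codon("".join(letters))
        if dc.has_stop:
            continue
        missing = len(target - dc.aa_set)
        off_target = len(dc.aa_set - target)
        exact = 0 if (missing == 0 and off_target == 0) else 1
        tvd = round(_tvd(dc.aa_freqs(), target_freqs), 12)
        key = (exact, missing, off_target, tvd, len(dc.codons))
        scored.append((key, dc))
    scored.sort(key=lambda kv: (kv[0], kv[1].triplet))
    best_key = scored[0][0]
    return [dc for key, dc in scored if key == best_key]


@dataclass
class PrimerDesign:
    """An assembled focused-library oligo (coding strand)."""

    coding: str
    flank5: str
    flank3: str
    position_map: dict[int, tuple[int, int]]  # peptide position -> [start, end) in coding
    sites: dict[str, str]
    antisense: str = ""
    flagged_positions: list[int] = field(default_factory=list)


def design_from_logo(
    logo: ClusterLogo,
    target_length: int | None = None,
    fixed_codon_table: dict[str, str] | None = None,
    extension_split: tuple[int, int] | None = None,
    forced_fixed: dict[int, str] | None = None,
    f_fixed: float | None = None,
    f_cum: float | None = None,
) -> LibraryDesignSpec:
    """Turn a classified logo into a focused-library design.

    Fixed positions keep defined codons, partial positions get the best
    semi-degenerate codon weighted by the logo frequencies, and free
    positions become trimer-randomized. When ``target_length`` exceeds the
    logo length, the added fully randomized residues are split between the
    two ends (default as even as possible, extra residue 3'), e.g. 3+3
    when extending a 14-mer core to 20.
    """
    table = fixed_codon_table or DEFAULT_CODON_TABLE
    if logo.classes is None:
        kwargs = {}
        if f_fixed is not None:
            kwargs["f_fixed"] = f_fixed
        if f_cum is not None:
            kwargs["f_cum"] = f_cum
        classify_positions(logo, forced_fixed=forced_fixed, **kwargs)
    classes: list[PositionClass] = list(logo.classes or [])

    target_length = target_length or logo.length
    added = target_length - logo.length
    if added < 0:
        raise ValueError("target length shorter than the logo")
    if extension_split is None:
        extension_split = (added // 2, added - added // 2)
    if sum(extension_split) != added:
        raise ValueError(f"extension split {extension_split} does not sum to {added}")

    positions: list[PositionSpec] = []
    flagged: list[int] = []
    index = 0
    for _ in range(extension_split[0]):
        index += 1
        positions.append(trimer_random(index))
    for core_pos, cls in enumerate(classes, start=1):
        index += 1
        if cls.kind == "fixed":
            positions.append(fixed_pos(index, cls.aas, table))
        elif cls.kind == "partial":
            freqs = {aa: float(logo.pwm.loc[core_pos, aa]) for aa in cls.aas}
            tier = best_degenerate_codon(set(cls.aas), freqs)
            best = tier[0]
            if best.aa_set != set(cls.aas):
                flagged.append(index)
            positions.append(choice_pos(index, "".join(sorted(best.aa_set)), best.triplet))
        else:
            positions.append(trimer_random(index))
    for _ in range(extension_split[1]):
        index += 1
        positions.append(trimer_random(index))

    staple = tuple(p.index for p in positions if p.kind == "fixed" and p.aas == "C")
    scaffold = tuple(p.index for p in positions if p.kind == "fixed" and p.aas == "A")
    if flagged:
        import warnings

        warnings.warn(
            f"no exact-cover stop-free codon at positions {flagged}; best partial cover used",
            stacklevel=2,
        )
    return LibraryDesignSpec(
        length=target_length,
        positions=positions,
        fixed_codon_table=dict(table),
        staple_positions=staple if len(staple) == 2 else None,
        scaffold_positions=scaffold,
    )


def assemble_primer(design: LibraryDesignSpec) -> PrimerDesign:
    """Concatenate flank5 + per-position codon specs + flank3.

    Verifies the KpnI motif on the coding strand and generates an
    antisense stub (reverse complement of the 3' flank plus vector
    context) carrying the EagI site for Klenow extension.
    """
    parts: list[str] = []
    position_map: dict[int, tuple[int, int]] = {}
    offset = len(design.flank5_dna)
    for pos in design.positions:
        spec = "X" if pos.codon_spec == "X" else pos.codon_spec
        position_map[pos.index] = (offset, offset + len(spec))
        parts.append(spec)
        offset += len(spec)
    coding = design.flank5_dna + "".join(parts) + design.flank3_dna
    if KPNI_MOTIF not in coding:
        raise ValueError("assembled coding strand lacks the KpnI motif")
    antisense = reverse_complement(design.flank3_dna + EAGI_TAIL)
    if EAGI_MOTIF not in antisense:
        raise ValueError("antisense stub lacks the EagI motif")
    return PrimerDesign(
        coding=coding,
        flank5=design.flank5_dna,
        flank3=design.flank3_dna,
        position_map=position_map,
        sites={"KpnI": KPNI_MOTIF, "EagI": EAGI_MOTIF},
        antisense=antisense,
    )


@dataclass(frozen=True)
class DiversityReport:
    theoretical_diversity: float
    match_prob: float
    expected_matches: float
    prob_at_least_one: float
    library_size: float


def diversity(
    design: LibraryDesignSpec,
    query_classes: list[PositionClass] | None = None,
    library_size: float = 1e8,
) -> DiversityReport:
    """Peptide-level diversity and logo-coverage statistics.

    ``theoretical_diversity`` is the product over positions of the number
    of allowed residues. With a query logo classification, ``match_prob``
    is the chance a uniformly drawn library member satisfies every favored
    constraint: product over positions of |favored ∩ allowed| / |allowed|
    (free query positions contribute 1).
    """
    div = 1.0
    for pos in design.positions:
        div *= len(set(pos.allowed))

    p = 1.0
    if query_classes is not None:
        if len(query_classes) != design.length:
            raise ValueError("query classification length must match the design")
        for pos, cls in zip(design.positions, query_classes):
            allowed = set(pos.allowed)
            if cls.kind == "free":
                continue
            favored = set(cls.aas)
            p *= len(favored & allowed) / len(allowed)
    n = library_size
    expected = n * p
    p_any = 1.0 if p >= 1.0 else float(-np.expm1(n * np.log1p(-p)))
    return DiversityReport(
        theoretical_diversity=div,
        match_prob=p,
        expected_matches=expected,
        prob_at_least_one=float(p_any),
        library_size=n,
    )
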
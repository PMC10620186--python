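"""Degenerate-codon optimization, primer assembly, and diversity."""

import itertools

import numpy as np
import pytest

from heliscreen.clustering import PositionClass, build_logo, Cluster, classify_positions
from heliscreen.design import naive_design, pr21_design
from heliscreen.genetics import IUPAC_DNA, RANDOM_ALPHABET, translate
from heliscreen.library_design import (
    assemble_primer,
    best_degenerate_codon,
    design_from_logo,
    diversity,
    expand_degenerate_codon,
)
from heliscreen.seq_io import match_design

PR21_CODING = (
    "CATGCCCGGGTACCTTTCTATTCTCACTCTGCGCCG"
    "XXXXTGGGAATGTXGAAGCAGCAWTKXTGTXTWTTWTXXX"
    "GGTGGTTCTGGCGCAGGTCGTGGTTC"
)


class TestExpandDegenerateCodon:
    @pytest.mark.parametrize(
        "triplet,codons,aas",
        [
            ("WTK", {"ATG", "ATT", "TTG", "TTT"}, {"M", "I", "L", "F"}),
            ("TWT", {"TAT", "TTT"}, {"Y", "F"}),
            ("RTT", {"ATT", "GTT"}, {"I", "V"}),
            ("TGG", {"TGG"}, {"W"}),
        ],
    )
    def test_worked_examples(self, triplet, codons, aas):
        dc = expand_degenerate_codon(triplet)
        assert set(dc.codons) == codons
        assert dc.aa_set == aas

    def test_expansion_size_is_product_of_degeneracies(self):
        dc = expand_degenerate_codon("NNK")
        assert len(dc.codons) == 4 * 4 * 2
        assert all(translate(c) for c in dc.codons)

    def test_invalid_code_raises(self):
        with pytest.raises(ValueError):
            expand_degenerate_codon("WTZ")


def brute_force_exact_covers(target: set[str]) -> set[str]:
    """Independent enumeration of all 15^3 triplets: stop-free exact covers."""
    covers = set()
    for letters in itertools.product("ACGTRYSWKMBDHVN", repeat=3):
        triplet = "".join(letters)
        codons = ["".join(c) for c in itertools.product(*[IUPAC_DNA[x] for x in triplet])]
        aas = {translate(c) for c in codons}
        if "*" not in aas and aas == target:
            covers.add(triplet)
    return covers


class TestBestDegenerateCodon:
    @pytest.mark.parametrize(
        "target,expected_member",
        [({"F", "L", "I", "M"}, "WTK"), ({"Y", "F"}, "TWT"), ({"V", "I"}, "RTT")],
    )
    def test_worked_tiers(self, target, expected_member):
        tier = best_degenerate_codon(target)
        triplets = {dc.triplet for dc in tier}
        assert expected_member in triplets
        # every tier member is an exact cover, cross-checked by brute force
        covers = brute_force_exact_covers(target)
        assert triplets <= covers
        for dc in tier:
            assert dc.aa_set == target

    def test_singleton(self):
        tier = best_degenerate_codon({"W"})
        assert tier[0].triplet == "TGG"

    def test_no_stop_codons_anywhere(self):
        for target in [{"Y", "Q"}, {"W", "S"}, {"E", "D", "Q"}]:
            for dc in best_degenerate_codon(target):
                assert not dc.has_stop

    def test_frequency_weighting_breaks_ties_consistently(self):
        uniform = best_degenerate_codon({"F", "L"})[0]
        skewed = best_degenerate_codon({"F", "L"}, {"F": 0.9, "L": 0.1})[0]
        assert uniform.aa_set == skewed.aa_set == {"F", "L"}

    def test_partial_cover_when_no_exact_exists(self):
        target = {"M", "W", "H", "D", "Q"}
        assert not brute_force_exact_covers(target)  # genuinely uncoverable set
        best = best_degenerate_codon(target)[0]
        assert not best.has_stop
        # ranking still prefers covering as much of the target as possible
        assert len(target - best.aa_set) < len(target)


def balanced_members(design, n: int = 64) -> list[str]:
    """Family members realizing a design with exactly uniform per-position
    frequencies (each allowed residue appears n/|allowed| times)."""
    members = []
    for i in range(n):
        members.append(
            "".join(pos.allowed[(i + pos.index) % len(pos.allowed)] for pos in design.positions)
        )
    return members


class TestDesignFromLogo:
    def make_pr21_logo(self):
        """A logo whose members realize the worked 20-mer cluster."""
        design = pr21_design()
        logo = build_logo(Cluster(1, balanced_members(design)))
        classify_positions(logo, forced_fixed={7: "C", 10: "A", 11: "A", 14: "C"})
        return logo

    def test_worked_cluster_codons(self):
        logo = self.make_pr21_logo()
        spec = design_from_logo(logo, target_length=20)
        codons = [p.codon_spec for p in spec.positions]
        assert codons[4:7] == ["TGG", "GAA", "TGT"]  # W5 E6 C7
        assert codons[8:11] == ["GAA", "GCA", "GCA"]  # E9 A10 A11
        assert codons[13] == "TGT"  # C14
        # degenerate positions: the chosen codon sits in the exact-cover tier
        assert codons[11] in {dc.triplet for dc in best_degenerate_codon(set("FILM"))}
        for i in (15, 16):
            assert codons[i] in {dc.triplet for dc in best_degenerate_codon(set("FY"))}
        assert set(spec.positions[11].aas) == set("FILM")  # (F/I/L/M)12
        assert set(spec.positions[15].aas) == set("FY")  # (F/Y)16
        for i in (0, 1, 2, 3, 7, 12, 14, 17, 18, 19):
            assert codons[i] == "X"

    def test_extension_adds_six_randomized_flanks(self):
        design = naive_design()
        logo = build_logo(Cluster(1, balanced_members(design)))
        classify_positions(logo, forced_fixed={4: "C", 11: "C", 7: "A", 8: "A"})
        spec20 = design_from_logo(logo, target_length=20)
        assert spec20.length == 20
        added = [p for p in spec20.positions if p.index <= 3 or p.index >= 18]
        assert len(added) == 6
        assert all(p.kind == "trimer_random" for p in added)

    def test_all_fixed_logo_has_no_degenerate_codons(self):
        cl = Cluster(1, ["WECACHDE"] * 4)  # two cysteines keep the staple invariant
        logo = build_logo(cl)
        classify_positions(logo)
        spec = design_from_logo(logo)
        assert all(p.kind == "fixed" for p in spec.positions)
        assert not any(p.codon_spec == "X" for p in spec.positions)

    def test_roundtrip_recovers_generating_constraints(self):
        """Members generated from a known design, clustered and re-designed,
        reproduce that design's per-position constraints."""
        logo = self.make_pr21_logo()
        spec = design_from_logo(logo, target_length=20)
        original = pr21_design()
        for got, want in zip(spec.positions, original.positions):
            assert got.kind == want.kind, f"position {want.index}"
            assert set(got.aas) == set(want.aas)


class TestAssemblePrimer:
    def test_pr21_reconstruction_byte_for_byte(self):
        primer = assemble_primer(pr21_design())
        assert primer.coding == PR21_CODING

    def test_kpni_on_coding_and_eagi_on_antisense(self):
        primer = assemble_primer(pr21_design())
        assert "GGTACC" in primer.coding
        assert "CGGCCG" in primer.antisense

    def test_position_map_spans_translate_to_constraints(self):
        design = pr21_design()
        primer = assemble_primer(design)
        for pos in design.positions:
            start, end = primer.position_map[pos.index]
            span = primer.coding[start:end]
            assert span == pos.codon_spec if pos.codon_spec != "X" else span == "X"

    def test_instantiations_all_match_design(self):
        """Concrete peptides drawn from the assembled primer's degenerate
        spec are accepted by match_design."""
        design = pr21_design()
        rng = np.random.default_rng(9)
        for pep in design.sample_peptides(200, rng):
            assert match_design(pep, design)


class TestDiversity:
    def test_naive_14mer_diversity(self):
        report = diversity(naive_design())
        assert report.theoretical_diversity == pytest.approx(16**10)

    def test_logo_coverage_closed_form(self):
        # 8 variable positions fixed to single aas, 4 narrowed to 2-aa sets
        # (16-mer scaffold: 12 variable positions in total)
        design = naive_design(length=16)
        classes = []
        n_fixed = n_pair = 0
        for p in design.positions:
            if p.kind == "fixed":
                classes.append(PositionClass("fixed", p.aas))
            elif n_fixed < 8:
                classes.append(PositionClass("fixed", "W"))
                n_fixed += 1
            elif n_pair < 4:
                classes.append(PositionClass("partial", "FY"))
                n_pair += 1
        report = diversity(design, classes, library_size=1e8)
        assert report.match_prob == pytest.approx((1 / 16) ** 8 * (2 / 16) ** 4)
        assert report.expected_matches < 1
        assert report.expected_matches == pytest.approx(1e8 * report.match_prob)

    def test_all_fixed_design(self):
        cl = Cluster(1, ["WECACHDE"] * 4)
        logo = build_logo(cl)
        classify_positions(logo)
        spec = design_from_logo(logo)
        report = diversity(spec)
        assert report.theoretical_diversity == 1
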
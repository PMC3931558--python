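"""Marker maps, meiosis, crosses, mutagenesis: the genetic engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from supmap import sim
from supmap.genome import SparseGenome

from conftest import dosed_individual, het_individual, toy_variant


class TestMarkerMap:
    def test_count_sortedness_uniqueness(self):
        mm = sim.build_marker_map({"I": 1_000_000}, 10.0, np.random.default_rng(1))
        cm = mm.chroms["I"]
        assert cm.n_markers == 10
        assert np.all(np.diff(cm.positions) > 0)
        assert np.all(cm.allele_a != cm.allele_b)

    def test_zero_expected_markers_is_valid(self):
        mm = sim.build_marker_map({"I": 10_000}, 10.0, np.random.default_rng(1))
        assert mm.chroms["I"].n_markers == 0
        assert mm.n_markers == 0

    def test_deterministic_given_seed(self):
        a = sim.build_marker_map({"I": 2_000_000, "II": 1_000_000}, 20.0, 3)
        b = sim.build_marker_map({"I": 2_000_000, "II": 1_000_000}, 20.0, 3)
        for c in a.chroms:
            assert np.array_equal(a.chroms[c].positions, b.chroms[c].positions)
            assert np.array_equal(a.chroms[c].allele_b, b.chroms[c].allele_b)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="length"):
            sim.build_marker_map({"I": 0}, 10.0, np.random.default_rng(1))


class TestMeiosis:
    def test_homozygous_parent_gives_identical_gamete(self, small_map):
        parent = sim.make_founder(small_map, False)
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = sim.meiosis(parent, small_map, rng)
            assert not g["I"].alleles.any()

    def test_recombinant_fraction_two_markers(self):
        # markers at 25% and 75% of the chromosome: a uniform crossover falls
        # between them with probability 0.5
        mm = sim.MarkerMap({"I": sim.ChromosomeMarkers(
            "I", 1_000_000, np.array([250_000, 750_000]),
            np.array(["A", "A"]), np.array(["T", "T"]))})
        parent = het_individual(mm, None)
        rng = np.random.default_rng(11)
        rec = sum(
            g["I"].alleles[0] != g["I"].alleles[1]
            for g in (sim.meiosis(parent, mm, rng) for _ in range(10_000)))
        assert abs(rec / 10_000 - 0.50) < 0.02

    def test_single_marker_transmission_symmetry(self):
        mm = sim.MarkerMap({"I": sim.ChromosomeMarkers(
            "I", 1_000_000, np.array([400_000]), np.array(["A"]), np.array(["T"]))})
        parent = het_individual(mm, None)
        rng = np.random.default_rng(12)
        b = sum(int(sim.meiosis(parent, mm, rng)["I"].alleles[0])
                for _ in range(10_000))
        assert abs(b / 10_000 - 0.5) < 0.02

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 8), st.booleans())
    def test_conservation_every_gamete_allele_is_parental(self, seed, n_markers,
                                                          poisson):
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(
            np.arange(1, 100_000), size=n_markers, replace=False))
        mm = sim.MarkerMap({"I": sim.ChromosomeMarkers(
            "I", 100_000, positions,
            np.array(["A"] * n_markers), np.array(["T"] * n_markers))})
        h0 = sim.Haplotype(rng.random(n_markers) < 0.5,
                           frozenset({toy_variant(pos=int(rng.integers(1, 100_000)))}))
        h1 = sim.Haplotype(rng.random(n_markers) < 0.5, frozenset())
        parent = sim.Individual({"I": (h0, h1)})
        g = sim.meiosis(parent, mm, rng, "poisson" if poisson else "obligate")
        for j in range(n_markers):
            assert g["I"].alleles[j] in (h0.alleles[j], h1.alleles[j])
        assert g["I"].variants <= (h0.variants | h1.variants)


class TestCross:
    def test_selfing_heterozygote_segregates_one_quarter_homozygous(self, small_map):
        v = toy_variant()
        parent = dosed_individual(small_map, v, 1)
        rng = np.random.default_rng(2)
        offspring = sim.self_cross(parent, 2000, small_map, rng)
        frac = sum(o.variant_dose(v) == 2 for o in offspring) / 2000
        assert abs(frac - 0.25) < 0.03

    def test_homozygous_cross_is_identity(self, small_map):
        a = sim.make_founder(small_map, False)
        rng = np.random.default_rng(3)
        for child in sim.cross(a, a, 20, small_map, rng):
            assert not child.haplotypes["I"][0].alleles.any()
            assert not child.haplotypes["I"][1].alleles.any()

    def test_negative_offspring_rejected(self, small_map):
        a = sim.make_founder(small_map, False)
        with pytest.raises(ValueError):
            sim.cross(a, a, -1, small_map, np.random.default_rng(0))

    def test_incompatibility_kills_bb_sired_by_het(self, small_map):
        # selfing an A/B heterozygote with the paternal-effect rule: B/B
        # zygotes die, survivors segregate 1 A/A : 2 A/B at the locus
        model = sim.SelectionModel.recessive(
            incompatibility_enabled=True)
        model.incompatibility_locus = ("I", int(small_map.chroms["I"].positions[4]))
        parent = het_individual(small_map, None)
        rng = np.random.default_rng(4)
        idx = small_map.marker_index(*model.incompatibility_locus)
        offspring = sim.self_cross(parent, 6000, small_map, rng, model)
        genos = [sum(o.marker_genotype("I", idx)) for o in offspring]
        assert genos.count(2) == 0
        frac_aa = genos.count(0) / len(genos)
        assert abs(frac_aa - 1 / 3) < 0.025
        assert abs(len(offspring) / 6000 - 0.75) < 0.02


class TestBackcross:
    def test_zero_rounds_is_identity(self, small_map):
        line = sim.make_founder(small_map, False)
        out = sim.backcross_series(line, line, 0, None, small_map,
                                   np.random.default_rng(0))
        assert out is line

    def test_passenger_retention_halves_per_round(self):
        # 300 unlinked passengers, 4 rounds: expected retained fraction (1/2)^4
        lengths = {c: 4_000_000 for c in ("I", "II", "III", "IV", "V", "X")}
        mm = sim.build_marker_map(lengths, 2.0, np.random.default_rng(9))
        passengers = []
        rng = np.random.default_rng(10)
        for i in range(300):
            chrom = list(lengths)[i % 6]
            passengers.append(sim.EMSVariant(
                chrom, int(rng.integers(1, 4_000_000)), "G", "A", "passenger",
                "noncoding"))
        recurrent = sim.make_founder(mm, False)
        fracs = []
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            line = sim.make_founder(mm, False)
            haps = dict(line.haplotypes)
            for c in mm.chroms:
                h0, h1 = haps[c]
                vs = frozenset(v for v in passengers if v.chrom == c)
                haps[c] = (sim.Haplotype(h0.alleles, vs), h1)
            line = sim.Individual(haps)
            out = sim.backcross_series(line, recurrent, 4, None, mm, r)
            fracs.append(len(out.all_variants()) / 300)
        assert abs(np.mean(fracs) - 1 / 16) < 0.02

    def test_introgression_gaps_stay_a_type(self, small_map):
        donor = sim.make_founder(small_map, False)
        recurrent = sim.make_founder(small_map, True)
        gaps = [("I", 200_000, 600_000)]
        out = sim.backcross_series(donor, recurrent, 3, None, small_map,
                                   np.random.default_rng(5), introgression_gaps=gaps)
        cm = small_map.chroms["I"]
        in_gap = (cm.positions > 200_000) & (cm.positions <= 600_000)
        for hap in out.haplotypes["I"]:
            assert not hap.alleles[in_gap].any()


class TestMutagenize:
    def test_full_transition_fraction_forces_gc_to_at(self, toy_gene_setup):
        genome, gene, mm, rng = toy_gene_setup
        founder = sim.make_founder(mm, False)
        _, variants = sim.mutagenize(founder, 50, 1.0, [gene], genome, mm, rng,
                                     causal_gene=gene)
        for v in variants:
            assert v.ref in "GC" and v.alt == sim.TRANSITION[v.ref]

    def test_single_variant_is_causal_only(self, toy_gene_setup):
        genome, gene, mm, rng = toy_gene_setup
        founder = sim.make_founder(mm, False)
        mutant, variants = sim.mutagenize(founder, 1, 0.87, [gene], genome, mm, rng,
                                          causal_gene=gene)
        assert len(variants) == 1
        assert variants[0].role == "causal"
        assert variants[0].effect_truth == "missense"
        assert mutant.variant_dose(variants[0]) == 1  # heterozygous

    def test_transition_share_matches_spectrum(self):
        shares = []
        for seed in range(10):
            genome = SparseGenome({"I": 5_000_000}, seed=seed)
            rng = np.random.default_rng(seed)
            mm = sim.build_marker_map({"I": 5_000_000}, 2.0, rng, genome=genome)
            founder = sim.make_founder(mm, False)
            _, variants = sim.mutagenize(founder, 300, 0.87, [], genome, mm, rng)
            shares.append(
                np.mean([v.alt == sim.TRANSITION.get(v.ref) for v in variants]))
        assert abs(np.mean(shares) - 0.87) < 0.05

    def test_variants_avoid_marker_positions(self, toy_gene_setup):
        genome, gene, mm, rng = toy_gene_setup
        founder = sim.make_founder(mm, False)
        _, variants = sim.mutagenize(founder, 100, 0.87, [gene], genome, mm, rng,
                                     causal_gene=gene)
        marker_positions = mm.position_set()
        assert all((v.chrom, v.position) not in marker_positions for v in variants)

    def test_causal_locus_outside_genome_rejected(self):
        genome = SparseGenome({"I": 200_000, "Z": 200_000}, seed=1)
        rng = np.random.default_rng(1)
        stray = sim.make_gene("stray", "Z", 50_000, genome, rng)
        mm = sim.build_marker_map({"I": 200_000}, 10.0, rng)
        founder = sim.make_founder(mm, False)
        with pytest.raises(ValueError, match="causal"):
            sim.mutagenize(founder, 5, 0.87, [stray], genome, mm, rng,
                           causal_gene=stray)
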
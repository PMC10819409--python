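import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import PROFILES, random_guide
from oracles import oracle_find_sites
from crisprqc import (
    Contig,
    GuideQuery,
    SearchProfile,
    find_sites,
    iupac_match,
    reverse_complement,
)
from crisprqc.fixtures import PlantSpec, plant_sites, simulate_genome

dna = st.text(alphabet="ACGTN", min_size=1, max_size=60)


class TestIupac:
    @pytest.mark.parametrize(
        "base,code,expected",
        [
            ("G", "N", True),
            ("A", "V", True),
            ("T", "V", False),
            ("G", "V", True),  # Cas12a TTTV PAM admits TTTG
            ("G", "R", True),
            ("C", "Y", True),
            ("N", "N", False),  # masked genome bases match nothing
            ("N", "A", False),
        ],
    )
    def test_membership(self, base, code, expected):
        assert iupac_match(base, code) is expected

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            iupac_match("A", "X")


class TestReverseComplement:
    def test_plain_and_iupac(self):
        assert reverse_complement("AAGG") == "CCTT"
        assert reverse_complement("NGG") == "CCN"
        assert reverse_complement("TTTV") == "BAAA"

    @given(seq=dna)
    @settings(max_examples=50, deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("AXG")


class TestGuideValidation:
    def test_bad_protospacer_alphabet(self):
        with pytest.raises(ValueError):
            GuideQuery("g", "ACGN" * 5, "NGG", "three_prime")

    def test_bad_length(self):
        with pytest.raises(ValueError):
            GuideQuery("g", "ACGT", "NGG", "three_prime")

    def test_bad_profile_bounds(self):
        with pytest.raises(ValueError):
            SearchProfile("p", 9, 0)
        with pytest.raises(ValueError):
            SearchProfile("p", 3, 4)


def engine_map(genome, guide, profile):
    return {
        s.key: (s.mismatches, s.dna_bulge, s.rna_bulge)
        for s in find_sites(genome, guide, profile)
    }


class TestPlantedSites:
    def test_exact_plant_recovered_with_pam(self, cas9_guide):
        genome = simulate_genome(5, [2000])
        genome, _ = plant_sites(
            genome, cas9_guide, [PlantSpec(cas9_guide.guide_id, "ctg1", 101)], seed=2
        )
        sites = [
            s for s in find_sites(genome, cas9_guide, PROFILES["strict"])
            if s.interval.start == 101
        ]
        assert len(sites) == 1
        s = sites[0]
        assert (s.interval.end, s.strand, s.mismatches) == (120, "+", 0)
        assert s.pam_interval.start == 121 and len(s.pam_seq) == 3
        assert s.pam_seq.endswith("GG")

    def test_mismatch_threshold_boundary(self, cas9_guide):
        genome = simulate_genome(6, [2000])
        genome, _ = plant_sites(
            genome,
            cas9_guide,
            [PlantSpec(cas9_guide.guide_id, "ctg1", 101, n_mismatches=1)],
            seed=2,
        )
        at_plant = lambda prof: [
            s for s in find_sites(genome, cas9_guide, prof) if s.interval.start == 101
        ]
        assert len(at_plant(SearchProfile("m1", 1, 0))) == 1
        assert at_plant(SearchProfile("m1", 1, 0))[0].mismatches == 1
        assert at_plant(SearchProfile("m0", 0, 0)) == []

    def test_invalid_pam_suppresses_planted_placement(self, cas9_guide):
        """A perfect protospacer with a broken PAM is never reported at the
        planted placement (flanking bases may still licence shifted or
        bulged alignments with their own PAMs)."""
        genome = simulate_genome(7, [2000])
        genome, _ = plant_sites(
            genome,
            cas9_guide,
            [PlantSpec(cas9_guide.guide_id, "ctg1", 101, pam_valid=False)],
            seed=2,
        )
        for prof in PROFILES.values():
            assert not [
                s for s in find_sites(genome, cas9_guide, prof)
                if (s.interval.start, s.interval.end, s.strand) == (101, 120, "+")
            ]

    def test_five_prime_pam_site(self, cas12a_guide):
        genome = simulate_genome(8, [2000])
        genome, _ = plant_sites(
            genome, cas12a_guide, [PlantSpec(cas12a_guide.guide_id, "ctg1", 301)], seed=2
        )
        sites = [
            s for s in find_sites(genome, cas12a_guide, PROFILES["strict"])
            if s.interval.start == 301 and s.strand == "+"
        ]
        assert len(sites) == 1
        assert sites[0].pam_interval == type(sites[0].pam_interval)("ctg1", 297, 300, "+")

    @pytest.mark.parametrize("btype,blen", [("dna", 1), ("dna", 2), ("rna", 1), ("rna", 2)])
    def test_bulged_plants_need_bulge_budget(self, cas9_guide, btype, blen):
        genome = simulate_genome(9, [3000])
        genome, _ = plant_sites(
            genome,
            cas9_guide,
            [
                PlantSpec(
                    cas9_guide.guide_id, "ctg1", 501,
                    n_mismatches=1, bulge_type=btype, bulge_length=blen,
                )
            ],
            seed=3,
        )
        span = 20 + (blen if btype == "dna" else -blen)
        hit = [
            s for s in find_sites(genome, cas9_guide, PROFILES["bulged"])
            if s.interval.start == 501 and len(s.interval) == span
        ]
        assert len(hit) == 1
        assert (hit[0].dna_bulge if btype == "dna" else hit[0].rna_bulge) == blen
        assert hit[0].mismatches <= 1
        # the bulge-free profile cannot report this span
        assert all(
            len(s.interval) == 20
            for s in find_sites(genome, cas9_guide, PROFILES["loose"])
        )


class TestEngineProperties:
    def test_genome_of_ns_yields_nothing(self, cas9_guide):
        genome = [Contig("c1", "N" * 1000)]
        assert find_sites(genome, cas9_guide, PROFILES["bulged"]) == []

    def test_n_bases_block_sites(self, cas9_guide):
        genome = simulate_genome(5, [2000])
        genome, _ = plant_sites(
            genome, cas9_guide, [PlantSpec(cas9_guide.guide_id, "ctg1", 101)], seed=2
        )
        seq = genome[0].sequence
        broken = [Contig("ctg1", seq[:110] + "N" + seq[111:])]
        assert all(
            s.interval.start != 101
            for s in find_sites(broken, cas9_guide, PROFILES["strict"])
        )

    def test_short_contig_returns_empty(self, cas9_guide):
        assert find_sites([Contig("c", "ACGT" * 3)], cas9_guide, PROFILES["strict"]) == []

    def test_mismatch_monotonicity(self, small_genome):
        guide = random_guide(21)
        genome, _ = plant_sites(
            small_genome, guide,
            [PlantSpec(guide.guide_id, "ctg1", 401, n_mismatches=4)], seed=4,
        )
        for b in (0, 2):
            prev: set = set()
            for m in range(6):
                cur = set(engine_map(genome, guide, SearchProfile("p", m, b)))
                assert prev <= cur
                prev = cur

    def test_bulge_monotonicity(self, small_genome):
        guide = random_guide(22)
        genome, _ = plant_sites(
            small_genome, guide,
            [PlantSpec(guide.guide_id, "ctg1", 901, n_mismatches=2,
                       bulge_type="dna", bulge_length=2)], seed=4,
        )
        m0 = set(engine_map(genome, guide, SearchProfile("p", 4, 0)))
        m1 = set(engine_map(genome, guide, SearchProfile("p", 4, 1)))
        m2 = set(engine_map(genome, guide, SearchProfile("p", 4, 2)))
        assert m0 <= m1 <= m2

    def test_strand_mirror_symmetry(self):
        guide = random_guide(23)
        genome = simulate_genome(23, [1500])
        genome, _ = plant_sites(
            genome, guide,
            [PlantSpec(guide.guide_id, "ctg1", 301, n_mismatches=2),
             PlantSpec(guide.guide_id, "ctg1", 1101, strand="-", n_mismatches=1)],
            seed=5,
        )
        L = len(genome[0])
        mirrored = [Contig("ctg1", reverse_complement(genome[0].sequence))]
        fwd = engine_map(genome, guide, PROFILES["bulged"])
        rev = engine_map(mirrored, guide, PROFILES["bulged"])
        flip = {"+": "-", "-": "+"}
        remapped = {
            (c, L - e + 1, L - s + 1, flip[st_]): v for (c, s, e, st_), v in rev.items()
        }
        assert fwd == remapped


class TestOracleEquivalence:
    """find_sites must agree exactly with exhaustive enumeration."""

    @pytest.mark.parametrize("seed", range(6))
    def test_planted_genomes_all_profiles(self, seed):
        rng = np.random.default_rng(seed)
        guide = random_guide(seed + 100)
        genome = simulate_genome(seed, [1500])
        specs = []
        for k, pos in enumerate((101, 601, 1101)):
            btype = ("none", "dna", "rna")[k]
            specs.append(
                PlantSpec(
                    guide.guide_id, "ctg1", pos,
                    strand="+" if k % 2 else "-",
                    n_mismatches=int(rng.integers(0, 5)),
                    bulge_type=btype,
                    bulge_length=0 if btype == "none" else int(rng.integers(1, 3)),
                )
            )
        genome, _ = plant_sites(genome, guide, specs, seed=seed)
        for prof in PROFILES.values():
            expected = oracle_find_sites(genome, guide, prof.max_mismatches, prof.max_bulge)
            assert engine_map(genome, guide, prof) == expected

    def test_guide_lifted_from_genome(self):
        genome = simulate_genome(42, [1200])
        proto = genome[0].sequence[500:520]
        guide = GuideQuery("lifted", proto, "NGG", "three_prime")
        prof = SearchProfile("p", 5, 2)
        assert engine_map(genome, guide, prof) == oracle_find_sites(genome, guide, 5, 2)

    def test_cas12a_style_guide(self):
        genome = simulate_genome(43, [1200])
        guide = GuideQuery("c12", "TTGACCATGAAGTCAGGATC", "TTTV", "five_prime")
        prof = SearchProfile("p", 5, 2)
        assert engine_map(genome, guide, prof) == oracle_find_sites(genome, guide, 5, 2)
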
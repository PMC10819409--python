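import pytest

from conftest import random_guide
from oracles import rc
from crisprqc import (
    Contig,
    CrossrefConfig,
    GenomicInterval,
    GuideQuery,
    OfftargetSite,
    crossref_sites,
    string_search_screen,
)
from test_variant_screen import make_record


def make_site(contig="c1", start=10_150, end=10_172, strand="+"):
    return OfftargetSite(
        guide_id="g",
        interval=GenomicInterval(contig, start, end, strand),
        strand=strand,
        mismatches=2,
        dna_bulge=0,
        rna_bulge=0,
        pam_interval=GenomicInterval(contig, end + 1, end + 3, strand),
        pam_seq="AGG",
        aligned_genomic_seq="A" * (end - start + 1),
        sources={"p"},
    )


class TestCrossref:
    def test_hit_within_window_with_distance(self):
        v = make_record(pos=10_000)
        site = make_site(start=10_150, end=10_172)
        (hit,) = crossref_sites([v], [site])
        assert hit.distance == 150
        assert hit.label == "off_target_candidate"

    def test_no_hit_beyond_window(self):
        v = make_record(pos=10_000)
        assert crossref_sites([v], [make_site(start=10_500, end=10_522)]) == []

    def test_window_zero_requires_overlap(self):
        v = make_record(pos=10_160)
        cfg = CrossrefConfig(window=0)
        assert len(crossref_sites([v], [make_site()], config=cfg)) == 1
        v2 = make_record(pos=10_149)
        assert crossref_sites([v2], [make_site()], config=cfg) == []

    def test_site_span_includes_pam(self):
        # variant exactly window bp from the PAM end, farther from protospacer
        v = make_record(pos=10_375)
        site = make_site(start=10_150, end=10_172)  # PAM 10173-10175
        (hit,) = crossref_sites([v], [site])
        assert hit.distance == 200

    def test_on_target_labeling_radius(self):
        target = GenomicInterval("c1", 10_100, 10_119)
        near = make_record(pos=10_050)
        far = make_record(pos=12_500)
        hits = crossref_sites([near, far], [make_site()], target_interval=target)
        labels = {h.variant.interval.start: h.label for h in hits}
        assert labels[10_050] == "on_target"
        assert labels[12_500] == "off_target_candidate" if 12_500 in labels else True

    def test_unknown_contig_warns_and_unlinks(self):
        odd = make_record(pos=100, contig="cX")
        with pytest.warns(UserWarning, match="absent"):
            hits = crossref_sites([odd], [make_site()])
        assert hits == []

    def test_shrinking_window_never_adds_hits(self):
        variants = [make_record(pos=p) for p in (10_000, 10_100, 10_400)]
        sites = [make_site()]
        wide = crossref_sites(variants, sites, config=CrossrefConfig(window=300))
        narrow = crossref_sites(variants, sites, config=CrossrefConfig(window=100))
        wide_keys = {(h.variant.interval.start, h.site.key) for h in wide}
        narrow_keys = {(h.variant.interval.start, h.site.key) for h in narrow}
        assert narrow_keys <= wide_keys


def plant_in_flank(guide, variant_pos, offset, n_mm=0, orientation="plus", length=3000):
    """Background of A's with the guide (possibly mutated/reverse-complemented)
    written at variant_pos + offset."""
    proto = guide.protospacer
    mutated = list(proto)
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for k in range(n_mm):
        mutated[2 + 3 * k] = swap[mutated[2 + 3 * k]]
    text = "".join(mutated)
    if orientation == "minus":
        text = rc(text)
    seq = list("A" * length)
    start0 = variant_pos - 1 + offset
    seq[start0 : start0 + len(text)] = text
    return [Contig("c1", "".join(seq))]


class TestStringSearch:
    guide = GuideQuery("g", "GCGTCGATTGCATCGGATCC", "NGG", "three_prime")

    def test_planted_match_downstream(self):
        v = make_record(pos=1000)
        genome = plant_in_flank(self.guide, 1000, 100, n_mm=2)
        hits = string_search_screen(genome, self.guide, [v])
        hits = [h for h in hits if h.mismatches == 2]
        assert len(hits) == 1
        assert hits[0].orientation == "plus"
        assert hits[0].match_interval.start == 1100

    def test_five_mismatches_not_reported(self):
        v = make_record(pos=1000)
        genome = plant_in_flank(self.guide, 1000, 100, n_mm=5)
        assert all(
            h.mismatches <= 4
            for h in string_search_screen(genome, self.guide, [v])
        )
        assert not any(
            h.match_interval.start == 1100 and h.orientation == "plus"
            for h in string_search_screen(genome, self.guide, [v])
        )

    def test_reverse_complement_plant_found_as_minus(self):
        v = make_record(pos=1000)
        genome = plant_in_flank(self.guide, 1000, -150, orientation="minus")
        hits = [
            h for h in string_search_screen(genome, self.guide, [v])
            if h.mismatches == 0
        ]
        assert len(hits) == 1
        assert hits[0].orientation == "minus"
        assert hits[0].match_interval.start == 850

    def test_no_pam_required(self):
        # guide planted with no PAM anywhere near: string search still hits
        v = make_record(pos=1000)
        genome = plant_in_flank(self.guide, 1000, 50)
        assert any(
            h.mismatches == 0 for h in string_search_screen(genome, self.guide, [v])
        )

    def test_matches_brute_force_window_scan(self):
        v = make_record(pos=1000)
        genome = plant_in_flank(self.guide, 1000, 120, n_mm=3)
        got = {
            (h.match_interval.start, h.orientation, h.mismatches)
            for h in string_search_screen(genome, self.guide, [v])
        }
        # independent scan of the extracted window
        seq = genome[0].sequence
        lo, hi = 1000 - 200, 1000 + 200
        expected = set()
        for orientation, pat in (("plus", self.guide.protospacer),
                                 ("minus", rc(self.guide.protospacer))):
            for s in range(lo, hi - len(pat) + 2):
                sub = seq[s - 1 : s - 1 + len(pat)]
                mm = sum(a != b for a, b in zip(sub, pat))
                if mm <= 4:
                    expected.add((s, orientation, mm))
        assert got == expected

    def test_variant_beyond_contig_is_error(self):
        v = make_record(pos=5000)
        genome = [Contig("c1", "ACGT" * 100)]
        with pytest.raises(ValueError, match="beyond"):
            string_search_screen(genome, self.guide, [v])

    def test_superset_of_ungapped_low_mismatch_crossref(self):
        """Any variant within range of an ungapped <=4-mm predicted site is
        also recovered by the PAM-free string search."""
        guide = random_guide(55)
        from crisprqc.fixtures import PlantSpec, plant_sites, simulate_genome
        from crisprqc import predict_offtargets

        genome = simulate_genome(55, [5000])
        genome, _ = plant_sites(
            genome, guide,
            [PlantSpec(guide.guide_id, "ctg1", 1001, n_mismatches=3)], seed=6,
        )
        sites = [
            s for s in predict_offtargets(genome, guide)
            if s.mismatches <= 4 and s.dna_bulge == 0 and s.rna_bulge == 0
        ]
        assert sites
        for site in sites:
            v = make_record(pos=max(1, site.interval.start - 100), contig="ctg1")
            hits = string_search_screen(genome, guide, [v])
            assert any(h.match_interval.start == site.interval.start for h in hits)
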
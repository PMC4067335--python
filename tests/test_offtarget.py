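import pytest

from sgdesign.fixtures import PlantCopy, PlantSpec, make_toy_genome, random_guide
from sgdesign.offtarget import (
    OfftargetHit,
    brute_force_scan,
    count_offtargets,
    search_offtargets,
)
from sgdesign.seqcore import DnaSequence, Genome, revcomp

from conftest import random_dna


class FakeGuide:
    def __init__(self, guide, guide_id="g1"):
        self.guide = guide
        self.guide_id = guide_id


GUIDE = "GACGTTAAACCGGATTACCA"


def genome_from(seqs: dict) -> Genome:
    return Genome({name: DnaSequence(name, s) for name, s in seqs.items()})


def hit_keys(hits):
    return [(h.chrom, h.start, h.end, h.strand, h.n_mismatch, h.pam_class) for h in hits]


class TestPlantedSites:
    def test_exact_ngg_site_found(self):
        genome, _ = make_toy_genome(
            7, 1, 1000, (PlantSpec(GUIDE, (PlantCopy("chr1", 101, "+"),)),)
        )
        hits = search_offtargets([FakeGuide(GUIDE)], genome, 0)
        planted = [h for h in hits if (h.start, h.strand) == (101, "+")]
        assert len(planted) == 1
        assert planted[0].n_mismatch == 0
        assert planted[0].pam_class == "NGG"
        assert planted[0].site_seq == GUIDE + "AGG"

    def test_nag_pam_tolerated_with_zero_mismatches(self):
        genome, _ = make_toy_genome(
            7, 1, 1000, (PlantSpec(GUIDE, (PlantCopy("chr1", 101, "+", pam="TAG"),)),)
        )
        hits = search_offtargets([FakeGuide(GUIDE)], genome, 0)
        planted = [h for h in hits if (h.start, h.strand) == (101, "+")]
        assert len(planted) == 1
        assert planted[0].n_mismatch == 0
        assert planted[0].pam_class == "NAG"

    @pytest.mark.parametrize("pam", ["TCG", "ATG", "AGA", "AGT", "AGC"])
    def test_rejected_pam_classes_never_emitted(self, pam):
        genome, _ = make_toy_genome(
            7, 1, 1000, (PlantSpec(GUIDE, (PlantCopy("chr1", 101, "+", pam=pam),)),)
        )
        hits = search_offtargets([FakeGuide(GUIDE)], genome, 5)
        assert not [h for h in hits if (h.start, h.strand) == (101, "+")]

    def test_minus_strand_plant_found_with_minus_strand_coordinates(self):
        genome, _ = make_toy_genome(
            9,
            1,
            500,
            (PlantSpec(GUIDE, (PlantCopy("chr1", 201, "-", frozenset({5, 17})),)),),
        )
        hits = search_offtargets([FakeGuide(GUIDE)], genome, 2)
        planted = [h for h in hits if (h.start, h.end) == (201, 223)]
        assert len(planted) == 1
        assert planted[0].strand == "-"
        assert planted[0].mismatch_positions == frozenset({5, 17})

    def test_mismatch_positions_numbered_pam_proximal(self):
        # mutate guide position 1 (the base adjacent to the PAM)
        genome, _ = make_toy_genome(
            11, 1, 500, (PlantSpec(GUIDE, (PlantCopy("chr1", 101, "+", frozenset({1})),)),)
        )
        (hit,) = [
            h
            for h in search_offtargets([FakeGuide(GUIDE)], genome, 1)
            if h.start == 101
        ]
        assert hit.mismatch_positions == frozenset({1})
        # rendered site: only the PAM-adjacent base is lowercase
        assert hit.site_seq[19].islower()
        assert hit.site_seq[:19].isupper() and hit.site_seq[20:].isupper()

    def test_genome_n_never_matches(self):
        seq = "T" * 30 + GUIDE[:10] + "N" + GUIDE[11:] + "AGG" + "T" * 30
        genome = genome_from({"c": seq})
        hits = search_offtargets([FakeGuide(GUIDE)], genome, 1)
        planted = [h for h in hits if h.start == 31]
        assert len(planted) == 1
        assert planted[0].n_mismatch == 1
        hits0 = search_offtargets([FakeGuide(GUIDE)], genome, 0)
        assert not [h for h in hits0 if h.start == 31]


class TestBruteForceScan:
    def test_empty_and_too_short_genomes(self):
        assert brute_force_scan(FakeGuide(GUIDE), genome_from({"c": "ACGT"})) == []

    def test_genome_equal_to_site_only(self):
        genome = genome_from({"c": GUIDE + "TGG"})
        hits = brute_force_scan(FakeGuide(GUIDE), genome, 0)
        assert hit_keys(hits) == [("c", 1, 23, "+", 0, "NGG")]

    def test_equivalence_with_indexed_engine_on_random_draws(self, rng):
        for _ in range(25):
            k = int(rng.integers(0, 6))
            guide = random_guide(rng)
            seqs = {
                "c1": random_dna(rng, int(rng.integers(200, 3000))),
                "c2": random_dna(rng, int(rng.integers(50, 500))),
            }
            # plant near-copies so non-trivial hits exist
            mm = frozenset(int(p) for p in rng.choice(20, size=k, replace=False) + 1)
            genome, _ = make_toy_genome(
                int(rng.integers(1 << 30)),
                1,
                2000,
                (PlantSpec(guide, (PlantCopy("chr1", 50, "+", mm),)),),
            )
            seqs["c3"] = genome.chromosomes["chr1"].seq
            g = genome_from(seqs)
            fast = search_offtargets([FakeGuide(guide)], g, k)
            slow = brute_force_scan(FakeGuide(guide), g, k)
            assert [h.key() for h in fast] == [h.key() for h in slow]
            assert [h.site_seq for h in fast] == [h.site_seq for h in slow]
            assert [h.mismatch_positions for h in fast] == [
                h.mismatch_positions for h in slow
            ]


class TestEngineProperties:
    def test_monotone_in_k(self, rng):
        g = genome_from({"c": random_dna(rng, 4000)})
        guide = FakeGuide(random_guide(rng))
        prev: set = set()
        for k in range(6):
            now = {h.key() for h in search_offtargets([guide], g, k)}
            assert prev <= now
            prev = now

    def test_strand_symmetry_under_genome_revcomp(self, rng):
        seq = random_dna(rng, 3000)
        guide = FakeGuide(random_guide(rng))
        fwd = search_offtargets([guide], genome_from({"c": seq}), 5)
        rev = search_offtargets([guide], genome_from({"c": revcomp(seq)}), 5)
        n = len(seq)
        mirrored = {
            (n - h.end + 1, n - h.start + 1, "-" if h.strand == "+" else "+")
            for h in rev
        }
        assert {(h.start, h.end, h.strand) for h in fwd} == mirrored

    def test_both_strands_reported_independently(self):
        # the guide's site and its reverse complement planted at two loci
        seq = "T" * 10 + GUIDE + "AGG" + "T" * 10 + "CCT" + revcomp(GUIDE) + "T" * 10
        genome = genome_from({"c": seq})
        hits = search_offtargets([FakeGuide(GUIDE)], genome, 0)
        assert len(hits) == 2
        assert {h.strand for h in hits} == {"+", "-"}

    def test_chromosome_end_windows_skipped(self):
        # site truncated by the chromosome end must not be reported
        genome = genome_from({"c": "T" * 5 + GUIDE + "AG"})  # PAM cut short
        assert search_offtargets([FakeGuide(GUIDE)], genome, 0) == []

    def test_no_guides_no_hits(self):
        assert search_offtargets([], genome_from({"c": "ACGT" * 50}), 5) == []


class TestCountOfftargets:
    def test_counts_include_on_target_and_unknown_id_is_zero(self):
        genome, _ = make_toy_genome(
            13,
            1,
            2000,
            (
                PlantSpec(
                    GUIDE,
                    (
                        PlantCopy("chr1", 101, "+"),
                        PlantCopy("chr1", 301, "+"),
                        PlantCopy("chr1", 501, "-"),
                    ),
                ),
            ),
        )
        hits = search_offtargets([FakeGuide(GUIDE, "g7")], genome, 0)
        assert count_offtargets(hits, "g7") == 3
        assert count_offtargets(hits, "nope") == 0
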
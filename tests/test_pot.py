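from itertools import combinations

import pytest

from sgdesign.offtarget import OfftargetHit
from sgdesign.pot import (
    EXCLUDED,
    PERFECT,
    GuideReport,
    RegionScheme,
    build_reports,
    classify_hit,
    rank_risk,
    select_guides,
    write_pot_reports,
)


def make_hit(mm, pam_class="NGG", guide_id="g", L=20, chrom="c", start=1):
    mm = frozenset(mm)
    site = "".join(
        "a" if (L - j) in mm else "A" for j in range(L)
    ) + ("AGG" if pam_class == "NGG" else "AAG")
    return OfftargetHit(
        guide_id=guide_id,
        chrom=chrom,
        start=start,
        end=start + L + 2,
        strand="+",
        site_seq=site,
        mismatch_positions=mm,
        n_mismatch=len(mm),
        pam_class=pam_class,
    )


class TestClassifyHit:
    @pytest.mark.parametrize(
        "mm,expected",
        [
            ({15, 18}, "I"),  # all mismatches in region III
            ({9, 14, 20}, "II"),  # region I identical, one in region II
            ({3}, "III"),  # at least one mismatch in region I
            ({2, 8, 13, 19}, EXCLUDED),  # region-I mismatch with n=4: no type fits
            ({13}, "I"),
            ({20}, "I"),
            ({8}, "II"),
            ({12, 13, 14, 15, 16}, "II"),
            ({1, 2, 3}, "III"),
            ({7, 8, 9, 10}, EXCLUDED),
            ({1, 2, 3, 4, 5}, EXCLUDED),
        ],
    )
    def test_type_assignment(self, mm, expected):
        assert classify_hit(make_hit(mm)).pot_type == expected

    def test_perfect_ngg_is_not_a_pot(self):
        rec = classify_hit(make_hit(set(), "NGG"))
        assert rec.pot_type == PERFECT
        assert rec.risk_rank is None
        assert not rec.is_pot

    def test_perfect_nag_is_type_I_top_risk(self):
        rec = classify_hit(make_hit(set(), "NAG"))
        assert rec.pot_type == "I"
        assert rec.hit.n_mismatch == 0
        assert rec.risk_rank == 1

    def test_position_outside_guide_rejected(self):
        with pytest.raises(ValueError):
            classify_hit(make_hit({21}))

    def test_exhaustive_partition_small_sets(self):
        scheme = RegionScheme(20)
        for n in range(0, 4):
            for mm in combinations(range(1, 21), n):
                rec = classify_hit(make_hit(mm), scheme)
                assert rec.pot_type in {PERFECT, "I", "II", "III", EXCLUDED}

    def test_truncated_guide_regions_shift_with_length(self):
        scheme = RegionScheme(18)
        assert list(scheme.region_III) == list(range(13, 19))
        assert classify_hit(make_hit({13, 18}, L=18), scheme).pot_type == "I"
        assert classify_hit(make_hit({12}, L=18), scheme).pot_type == "II"
        assert classify_hit(make_hit({7}, L=18), scheme).pot_type == "III"

    def test_region_scheme_requires_13nt(self):
        with pytest.raises(ValueError):
            RegionScheme(12)


class TestRankRisk:
    def test_fewer_mismatches_more_dangerous_within_type(self):
        assert rank_risk("I", 1) < rank_risk("I", 3)

    def test_type_order_dominates_mismatch_count(self):
        assert rank_risk("I", 5) < rank_risk("III", 1)
        assert rank_risk("II", 5) < rank_risk("III", 1)
        assert rank_risk("I", 5) < rank_risk("II", 1)

    def test_equal_type_and_count_tie(self):
        a = classify_hit(make_hit({15, 16}))
        b = classify_hit(make_hit({14, 17}, start=500))
        assert a.risk_rank == b.risk_rank

    def test_excluded_records_get_no_rank(self):
        assert classify_hit(make_hit({1, 2, 3, 4})).risk_rank is None
        assert rank_risk(EXCLUDED, 4) is None

    def test_accepts_a_classified_record(self):
        rec = classify_hit(make_hit({15}))
        assert rank_risk(rec) == rec.risk_rank


class FakeGuide:
    def __init__(self, guide_id):
        self.guide_id = guide_id
        self.guide = "A" * 20


class TestSelection:
    def _reports(self, spec):
        """spec: guide_id -> list of (mm, pam_class) hits."""
        guides = [FakeGuide(gid) for gid in spec]
        records = [
            classify_hit(make_hit(mm, pam, guide_id=gid, start=17 + 23 * i))
            for gid, hits in spec.items()
            for i, (mm, pam) in enumerate(hits)
        ]
        return build_reports(guides, records), records

    def test_cascade_reasons_and_order(self):
        reports, _ = self._reports(
            {
                "junction": [],  # no genomic locus at all
                "multi": [(set(), "NGG"), (set(), "NGG")],
                "risky": [(set(), "NGG"), ({15}, "NGG")],  # 1-mm POT
                "good_busy": [(set(), "NGG"), ({13, 15, 17}, "NGG"), ({14, 16, 18}, "NGG")],
                "good_quiet": [(set(), "NGG"), ({13, 15, 17}, "NGG")],
            }
        )
        out = select_guides(reports)
        verdicts = {r.guide_id: (r.verdict, r.discard_reason) for r in out}
        assert verdicts["junction"] == ("discarded", "not_on_genome")
        assert verdicts["multi"] == ("discarded", "multi_locus")
        assert verdicts["risky"] == ("discarded", "has_1or2_mm_pot")
        assert verdicts["good_busy"] == ("kept", "none")
        assert verdicts["good_quiet"] == ("kept", "none")
        kept_ids = [r.guide_id for r in out if r.verdict == "kept"]
        assert kept_ids == ["good_quiet", "good_busy"]  # fewer POT sorts first

    def test_guide_with_only_high_mismatch_pots_kept(self):
        reports, _ = self._reports({"g": [(set(), "NGG"), ({13, 14, 15}, "NGG")]})
        (rep,) = select_guides(reports)
        assert rep.verdict == "kept"

    def test_nag_perfect_does_not_trigger_1or2_mm_discard(self):
        reports, _ = self._reports({"g": [(set(), "NGG"), (set(), "NAG")]})
        (rep,) = select_guides(reports)
        assert rep.verdict == "kept"
        assert rep.pot_counts["I"] == 1

    def test_excluded_hits_count_toward_total_ot_only(self):
        reports, _ = self._reports({"g": [(set(), "NGG"), ({1, 2, 3, 4}, "NGG")]})
        (rep,) = reports
        assert rep.total_ot == 2
        assert rep.pot_total == 0
        assert rep.n_perfect == 1

    def test_report_invariants(self):
        reports, _ = self._reports(
            {"a": [(set(), "NGG"), ({15}, "NGG"), ({1, 2, 3, 4}, "NGG")]}
        )
        (rep,) = reports
        assert rep.pot_total <= rep.total_ot
        assert rep.n_perfect <= rep.total_ot


class TestWritePotReports:
    def test_empty_records_create_header_only_folders(self, tmp_path):
        write_pot_reports([], tmp_path, reports=[])
        for t in ("I", "II", "III"):
            f = tmp_path / f"Type_{t}_POT" / "POT_records.txt"
            assert f.exists()
            assert f.read_text().startswith("site_seq\t")
            assert len(f.read_text().splitlines()) == 1
        assert (tmp_path / "Final_report" / "final_report.txt").exists()

    def test_three_types_distributed_to_their_folders(self, tmp_path):
        records = [
            classify_hit(make_hit({15}, guide_id="g1")),
            classify_hit(make_hit({9}, guide_id="g2", start=50)),
            classify_hit(make_hit({3}, guide_id="g3", start=100)),
        ]
        write_pot_reports(records, tmp_path)
        for t, gid in (("I", "g1"), ("II", "g2"), ("III", "g3")):
            lines = (tmp_path / f"Type_{t}_POT" / "POT_records.txt").read_text().splitlines()
            assert len(lines) == 2
            assert gid in lines[1]
        assert {p.name for p in (tmp_path / "Sort_POT_byID").iterdir()} == {
            "g1.txt",
            "g2.txt",
            "g3.txt",
        }

    def test_per_guide_files_lowercase_mismatches(self, tmp_path):
        records = [classify_hit(make_hit({15, 18}, guide_id="g1"))]
        write_pot_reports(records, tmp_path)
        body = (tmp_path / "Sort_POT_byID" / "g1.txt").read_text().splitlines()[1]
        site = body.split("\t")[0]
        assert [i for i, ch in enumerate(site) if ch.islower()] == [2, 5]  # L-18, L-15
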
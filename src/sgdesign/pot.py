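"""POT classification, risk ranking and the guide selection cascade.

The guide is segmented, counting from the PAM-proximal base, into region I
(positions 1-7), region II (8-12) and region III (13-L); regions I+II form
the seed, region III the non-seed.  Potential off-target cleavage sites
(POT) fall into three types by mismatch count and placement:

* Type I   — 1-5 mismatches, all in region III (seed identical);
* Type II  — 1-5 mismatches in regions II+III, at least one in region II,
  none in region I;
* Type III — 1-3 mismatches with at least one in region I.

A hit with a region-I mismatch and 4-5 mismatches total fits no type and is
excluded from the POT set (it still counts toward the raw off-target
total).  A 0-mismatch NGG hit is a perfect-match locus, never a POT; a
0-mismatch NAG hit is treated as Type I with n = 0 and carries the top risk
rank, since a perfect protospacer next to the tolerated NAG PAM is the most
cleavable non-canonical site.

Selection discards guides that (1) have no perfect genomic match, (2) match
multiple genomic loci perfectly, or (3) carry any POT with 1 or 2
mismatches; survivors are ordered by POT total, then raw off-target total.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .offtarget import OfftargetHit

__all__ = [
    "RegionScheme",
    "PotRecord",
    "GuideReport",
    "classify_hit",
    "rank_risk",
    "classify_all",
    "build_reports",
    "select_guides",
    "write_pot_reports",
]

PERFECT = "perfect"
EXCLUDED = "excluded"
POT_TYPES = ("I", "II", "III")


@dataclass(frozen=True)
class RegionScheme:
    """Seed/non-seed segmentation of an L-nt guide (PAM-proximal = position 1)."""

    guide_len: int = 20

    def __post_init__(self) -> None:
        if self.guide_len < 13:
            raise ValueError("region scheme requires guide_len >= 13")

    @property
    def region_I(self) -> range:
        return range(1, 8)

    @property
    def region_II(self) -> range:
        return range(8, 13)

    @property
    def region_III(self) -> range:
        return range(13, self.guide_len + 1)

    @property
    def seed(self) -> range:
        return range(1, 13)


@dataclass(frozen=True)
class PotRecord:
    """A classified off-target hit."""

    hit: OfftargetHit
    pot_type: str  # "I" | "II" | "III" | "excluded" | "perfect"
    risk_rank: int | None  # 1 = most dangerous; None for excluded/perfect

    @property
    def is_pot(self) -> bool:
        return self.pot_type in POT_TYPES


def classify_hit(hit: OfftargetHit, scheme: RegionScheme | None = None) -> PotRecord:
    """Assign the POT type of one hit; deterministic in (positions, n, PAM)."""
    scheme = scheme or RegionScheme(len(hit.site_seq) - 3)
    L = scheme.guide_len
    mm = hit.mismatch_positions
    n = hit.n_mismatch
    if any(p < 1 or p > L for p in mm):
        raise ValueError(
            f"mismatch positions {sorted(mm)} outside 1..{L} for hit at "
            f"{hit.chrom}:{hit.start}"
        )
    if n == 0:
        if hit.pam_class == "NGG":
            return PotRecord(hit, PERFECT, None)
        pot_type = "I"  # perfect protospacer, tolerated NAG PAM
    elif any(p in scheme.region_I for p in mm):
        pot_type = "III" if n <= 3 else EXCLUDED
    elif n > 5:
        pot_type = EXCLUDED
    elif any(p in scheme.region_II for p in mm):
        pot_type = "II"
    else:
        pot_type = "I"
    return PotRecord(hit, pot_type, rank_risk(pot_type, n))


def rank_risk(pot_type, n_mismatch: int | None = None) -> int | None:
    """Total risk order: Type I > II > III, fewer mismatches more dangerous.

    Accepts either ``(pot_type, n_mismatch)`` or a classified
    :class:`PotRecord`.  Returns a dense absolute rank (1 = most
    dangerous): Type I occupies ranks 1-6 (n = 0..5), Type II ranks 7-11
    (n = 1..5), Type III ranks 12-14 (n = 1..3).  Excluded and perfect
    records have no rank.
    """
    if isinstance(pot_type, PotRecord):
        pot_type, n_mismatch = pot_type.pot_type, pot_type.hit.n_mismatch
    if pot_type == "I":
        return 1 + n_mismatch
    if pot_type == "II":
        return 6 + n_mismatch
    if pot_type == "III":
        return 11 + n_mismatch
    return None


def classify_all(hits, scheme: RegionScheme | None = None) -> list[PotRecord]:
    return [classify_hit(h, scheme) for h in hits]


@dataclass
class GuideReport:
    """Per-guide aggregate of the off-target search and classification."""

    guide_id: str
    total_ot: int = 0
    n_perfect: int = 0
    pot_counts: dict = field(default_factory=lambda: {"I": 0, "II": 0, "III": 0})
    n_pot_1or2_mm: int = 0
    verdict: str = "kept"
    discard_reason: str = "none"

    @property
    def pot_total(self) -> int:
        return sum(self.pot_counts.values())


def build_reports(guides, records: list[PotRecord]) -> list[GuideReport]:
    """One :class:`GuideReport` per guide, in the order guides were given.

    Guides with no hit at all (e.g. exon-junction guides absent from the
    genome) still get a report, with zero counts.
    """
    by_id = {g.guide_id: GuideReport(g.guide_id) for g in guides}
    for rec in records:
        rep = by_id.setdefault(rec.hit.guide_id, GuideReport(rec.hit.guide_id))
        rep.total_ot += 1
        if rec.pot_type == PERFECT:
            rep.n_perfect += 1
        elif rec.is_pot:
            rep.pot_counts[rec.pot_type] += 1
            if rec.hit.n_mismatch in (1, 2):
                rep.n_pot_1or2_mm += 1
    return list(by_id.values())


def select_guides(reports: list[GuideReport]) -> list[GuideReport]:
    """Apply the selection cascade and order survivors first.

    Discards, in order: no perfect genomic match (``not_on_genome``),
    multiple perfect loci (``multi_locus``), any POT with 1-2 mismatches
    (``has_1or2_mm_pot``).  Survivors are sorted by (POT total ascending,
    raw off-target total ascending); discarded reports follow in input
    order.  Verdicts are written onto the (mutated) reports.
    """
    for rep in reports:
        if rep.n_perfect == 0:
            rep.verdict, rep.discard_reason = "discarded", "not_on_genome"
        elif rep.n_perfect > 1:
            rep.verdict, rep.discard_reason = "discarded", "multi_locus"
        elif rep.n_pot_1or2_mm > 0:
            rep.verdict, rep.discard_reason = "discarded", "has_1or2_mm_pot"
        else:
            rep.verdict, rep.discard_reason = "kept", "none"
    kept = sorted(
        (r for r in reports if r.verdict == "kept"),
        key=lambda r: (r.pot_total, r.total_ot),
    )
    return kept + [r for r in reports if r.verdict == "discarded"]


_POT_COLUMNS = [
    "site_seq",
    "n_mismatch",
    "guide_id",
    "chrom",
    "start",
    "end",
    "strand",
    "pam_class",
    "pot_type",
    "risk_rank",
]


def _pot_frame(records) -> pd.DataFrame:
    rows = [
        {
            "site_seq": r.hit.site_seq,
            "n_mismatch": r.hit.n_mismatch,
            "guide_id": r.hit.guide_id,
            "chrom": r.hit.chrom,
            "start": r.hit.start,
            "end": r.hit.end,
            "strand": r.hit.strand,
            "pam_class": r.hit.pam_class,
            "pot_type": r.pot_type,
            "risk_rank": r.risk_rank,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_POT_COLUMNS)


def write_pot_reports(records: list[PotRecord], out_dir, reports=None) -> None:
    """Write the per-type folders, per-guide POT files and the final report.

    Layout: ``Type_I_POT/``, ``Type_II_POT/``, ``Type_III_POT/`` each hold a
    ``POT_records.txt`` TSV (header-only when empty); ``Sort_POT_byID/``
    holds one TSV per guide with that guide's POT, mismatched bases in
    lowercase; if per-guide ``reports`` (post-selection) are given,
    ``Final_report/final_report.txt`` lists the kept guides.
    """
    os.makedirs(out_dir, exist_ok=True)
    pots = [r for r in records if r.is_pot]
    for t in POT_TYPES:
        d = os.path.join(out_dir, f"Type_{t}_POT")
        os.makedirs(d, exist_ok=True)
        _pot_frame([r for r in pots if r.pot_type == t]).to_csv(
            os.path.join(d, "POT_records.txt"), sep="\t", index=False
        )
    byid_dir = os.path.join(out_dir, "Sort_POT_byID")
    os.makedirs(byid_dir, exist_ok=True)
    by_guide: dict[str, list[PotRecord]] = {}
    for r in pots:
        by_guide.setdefault(r.hit.guide_id, []).append(r)
    for guide_id, recs in sorted(by_guide.items()):
        recs.sort(key=lambda r: (r.risk_rank, r.hit.chrom, r.hit.start))
        _pot_frame(recs).to_csv(
            os.path.join(byid_dir, f"{guide_id}.txt"), sep="\t", index=False
        )
    if reports is not None:
        final_dir = os.path.join(out_dir, "Final_report")
        os.makedirs(final_dir, exist_ok=True)
        rows = [
            {
                "guide_id": r.guide_id,
                "total_ot": r.total_ot,
                "n_perfect": r.n_perfect,
                "pot_I": r.pot_counts["I"],
                "pot_II": r.pot_counts["II"],
                "pot_III": r.pot_counts["III"],
                "pot_total": r.pot_total,
            }
            for r in reports
            if r.verdict == "kept"
        ]
        pd.DataFrame(
            rows,
            columns=[
                "guide_id",
                "total_ot",
                "n_perfect",
                "pot_I",
                "pot_II",
                "pot_III",
                "pot_total",
            ],
        ).to_csv(os.path.join(final_dir, "final_report.txt"), sep="\t", index=False)
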
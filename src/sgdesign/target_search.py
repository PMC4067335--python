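"""Protospacer discovery on input sequences.

A protospacer is an L-nt guide followed by an NGG PAM.  Three 5' patterns are
supported — GGX18, GX19 and X20 — reflecting the transcription-initiation
requirement of U6/T7 promoters (sgRNA should start with G).  Searching runs
on the sense strand, the antisense strand, or both; the paired mode
enumerates PAM-out guide pairs for the Cas9n (D10A) double-nicking strategy,
constrained by the signed offset between the two PAM-distal guide ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seqcore import DnaSequence, gc_percent, revcomp

__all__ = [
    "Protospacer",
    "GuidePair",
    "PATTERNS",
    "find_protospacers",
    "find_pairs",
    "guide_naming",
]

log = logging.getLogger(__name__)

#: 5' prefix each pattern imposes on the guide.
PATTERNS = {"GGX18": "GG", "GX19": "G", "X20": ""}


@dataclass(frozen=True)
class Protospacer:
    """One candidate target site (guide + PAM) on an input record.

    ``start``/``end`` are 1-based closed coordinates of the full guide+PAM
    window on the record's sense strand, regardless of which strand the
    site was found on.  ``guide`` and ``pam`` read 5'->3' on the site's own
    strand (``S`` = sense, ``A`` = antisense).
    """

    guide_id: str
    record_id: str
    strand: str  # "S" or "A"
    start: int
    end: int
    guide: str
    pam: str
    pattern: str
    gc: float

    @property
    def site(self) -> str:
        return self.guide + self.pam


@dataclass(frozen=True)
class GuidePair:
    """A PAM-out nickase pair: antisense member left, sense member right."""

    left: Protospacer  # antisense-strand member (sense strand reads CCN.. at its left edge)
    right: Protospacer  # sense-strand member (..NGG at its right edge)
    offset: int  # signed gap between the two PAM-distal guide ends, bp


def guide_naming(record_id: str, strand: str, ordinal: int) -> str:
    """Guide ID scheme ``{record_id}_{S|A}_{ordinal}`` (ordinal >= 1)."""
    if ordinal < 1:
        raise ValueError("guide ordinals are 1-based")
    if strand not in ("S", "A"):
        raise ValueError(f"strand must be 'S' or 'A', got {strand!r}")
    return f"{record_id}_{strand}_{ordinal}"


def _scan_one_strand(
    seq: str, pattern: str, guide_len: int, gc_min: float, gc_max: float
):
    """Yield (offset0, guide, pam, gc) for every qualifying window of ``seq``.

    Overlapping windows are all reported.  Guides containing N are dropped
    (they cannot be synthesized); the PAM's N position is unconstrained.
    """
    prefix = PATTERNS[pattern]
    L = guide_len
    w = L + 3
    n_dropped = 0
    for i in range(len(seq) - w + 1):
        if seq[i + L + 1 : i + L + 3] != "GG":
            continue
        guide = seq[i : i + L]
        if not guide.startswith(prefix):
            continue
        if "N" in guide:
            n_dropped += 1
            continue
        gc = gc_percent(guide)
        if not (gc_min <= gc <= gc_max):
            continue
        yield i, guide, seq[i + L : i + L + 3], gc
    if n_dropped:
        log.info("dropped %d candidate guides containing N", n_dropped)


def find_protospacers(
    record: DnaSequence,
    mode: str = "both",
    pattern: str = "X20",
    guide_len: int = 20,
    gc_min: float = 20.0,
    gc_max: float = 80.0,
) -> list[Protospacer]:
    """Find all protospacers in ``record`` under the given mode and pattern.

    ``mode`` is ``sense``/``s``, ``antisense``/``a`` or ``both``/``b``.
    Records shorter than guide_len + 3 yield an empty list.  Ordinals are
    assigned per strand in ascending start coordinate on the searched
    strand (for the antisense strand this is descending sense coordinate).
    """
    if guide_len < 15:
        raise ValueError("guide_len must be >= 15")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {sorted(PATTERNS)}")
    mode_key = mode[0].lower()
    if mode_key not in ("s", "a", "b"):
        raise ValueError(f"mode must be sense/antisense/both, got {mode!r}")

    L = guide_len
    n = len(record.seq)
    out: list[Protospacer] = []

    if mode_key in ("s", "b"):
        for ordinal, (i, guide, pam, gc) in enumerate(
            _scan_one_strand(record.seq, pattern, L, gc_min, gc_max), start=1
        ):
            out.append(
                Protospacer(
                    guide_id=guide_naming(record.id, "S", ordinal),
                    record_id=record.id,
                    strand="S",
                    start=i + 1,
                    end=i + L + 3,
                    guide=guide,
                    pam=pam,
                    pattern=pattern,
                    gc=gc,
                )
            )
    if mode_key in ("a", "b"):
        rc = revcomp(record.seq)
        for ordinal, (j, guide, pam, gc) in enumerate(
            _scan_one_strand(rc, pattern, L, gc_min, gc_max), start=1
        ):
            # window occupies rc[j : j+L+3]; map back to sense coordinates
            out.append(
                Protospacer(
                    guide_id=guide_naming(record.id, "A", ordinal),
                    record_id=record.id,
                    strand="A",
                    start=n - (j + L + 3) + 1,
                    end=n - j,
                    guide=guide,
                    pam=pam,
                    pattern=pattern,
                    gc=gc,
                )
            )
    return out


def pair_offset(left: Protospacer, right: Protospacer) -> int:
    """Signed distance between the PAM-distal (5') guide ends of a PAM-out pair.

    Both guides are projected onto sense-strand coordinates: the antisense
    member's guide ends (5' end, genomically rightmost) at ``left.end`` and
    the sense member's guide starts (5' end) at ``right.start``.  Abutting
    guides give 0; overlap gives negative values.
    """
    return right.start - left.end - 1


def find_pairs(
    record: DnaSequence,
    pattern: str = "X20",
    guide_len: int = 20,
    gc_min: float = 20.0,
    gc_max: float = 80.0,
    offset_min: int = -2,
    offset_max: int = 32,
) -> list[GuidePair]:
    """Enumerate PAM-out (antisense, sense) protospacer pairs.

    Every antisense/sense combination on the record whose offset falls in
    [offset_min, offset_max] is reported; one protospacer may appear in
    several pairs.  Both members individually satisfy the pattern and GC
    rules.
    """
    if offset_min > offset_max:
        raise ValueError(
            f"offset_min ({offset_min}) must not exceed offset_max ({offset_max})"
        )
    sites = find_protospacers(record, "both", pattern, guide_len, gc_min, gc_max)
    sense = [p for p in sites if p.strand == "S"]
    anti = [p for p in sites if p.strand == "A"]
    pairs = [
        GuidePair(a, s, pair_offset(a, s))
        for a in anti
        for s in sense
        if offset_min <= pair_offset(a, s) <= offset_max
    ]
    pairs.sort(key=lambda p: (p.left.start, p.right.start))
    return pairs
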
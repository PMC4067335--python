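"""Genome-wide k-mismatch off-target search.

For each guide, every genome window of guide_len + 3 nt on either strand is
a hit when (a) the Hamming distance between the window's guide region and
the guide is at most k and (b) the trailing 3-nt PAM reads NGG or NAG on
the hit strand.  The PAM's N position is never compared; a G->A change at
PAM position 2 (NGG -> NAG) is tolerated and not counted as a mismatch;
any other PAM (NCG/NTG/NGA/NGT/NGC/...) disqualifies the window.  Genome N
bases never match any guide base.

The production engine uses a pigeonhole seed partition: the guide is split
into k+1 contiguous segments, so any window within k mismatches must match
at least one segment exactly; exact segment occurrences are located through
a q-gram position index and candidates are verified by full Hamming
comparison.  This is lossless for <= k mismatches.  A naive per-window scan
(:func:`brute_force_scan`) is kept as an independent oracle.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .seqcore import Genome, revcomp

__all__ = [
    "OfftargetHit",
    "search_offtargets",
    "brute_force_scan",
    "count_offtargets",
]

_PAM_CLASS = {"GG": "NGG", "AG": "NAG"}


@dataclass(frozen=True)
class OfftargetHit:
    """One genome locus matching a guide within <= k mismatches.

    Coordinates are 1-based closed over the full guide+PAM window on the
    forward (sense) genome strand; ``site_seq`` reads 5'->3' on the hit
    strand with mismatched guide positions in lowercase.  Mismatch
    positions are numbered from the PAM-proximal base (position 1, adjacent
    to the PAM) to the PAM-distal base (position L).
    """

    guide_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    site_seq: str
    mismatch_positions: frozenset[int]
    n_mismatch: int
    pam_class: str  # "NGG" or "NAG"

    def key(self) -> tuple:
        return (self.guide_id, self.chrom, self.start, self.end, self.strand)


def _verify_window(window: str, guide: str):
    """Check one guide_len+3 window (on the hit strand) against a guide.

    Returns (mismatch_positions, pam_class, rendered_site) or None if the
    PAM is intolerable.  Position numbering is PAM-proximal = 1.
    """
    L = len(guide)
    pam = window[L : L + 3]
    pam_class = _PAM_CLASS.get(pam[1:3])
    if pam_class is None:
        return None
    mismatches = []
    rendered = list(window)
    for j in range(L):
        b = window[j]
        if b != guide[j] or b == "N":
            mismatches.append(L - j)
            rendered[j] = b.lower()
    return frozenset(mismatches), pam_class, "".join(rendered)


def _emit(guide_id, chrom, clen, pos0, strand, w, verified) -> OfftargetHit:
    """Build a hit from a verified window at 0-based scan position pos0."""
    mm, pam_class, rendered = verified
    if strand == "+":
        start, end = pos0 + 1, pos0 + w
    else:
        start, end = clen - (pos0 + w) + 1, clen - pos0
    return OfftargetHit(
        guide_id=guide_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        site_seq=rendered,
        mismatch_positions=mm,
        n_mismatch=len(mm),
        pam_class=pam_class,
    )


def _segments(L: int, k: int) -> list[tuple[int, int]]:
    """Split positions 0..L-1 into k+1 contiguous (offset, length) segments."""
    n_seg = min(k + 1, L)
    q, r = divmod(L, n_seg)
    segs, off = [], 0
    for i in range(n_seg):
        length = q + (1 if i < r else 0)
        segs.append((off, length))
        off += length
    return segs


def _qgram_index(seq: str, lengths: set[int]) -> dict[int, dict[str, list[int]]]:
    index: dict[int, dict[str, list[int]]] = {}
    for q in lengths:
        d = defaultdict(list)
        for i in range(len(seq) - q + 1):
            d[seq[i : i + q]].append(i)
        index[q] = d
    return index


def search_offtargets(guides, genome: Genome, k: int = 5) -> list[OfftargetHit]:
    """Pigeonhole-indexed search for all hits of ``guides`` in ``genome``.

    ``guides`` is an iterable of objects with ``guide_id`` and ``guide``
    attributes (e.g. :class:`~sgdesign.target_search.Protospacer`).  Both
    strands are searched independently; windows overhanging chromosome ends
    are skipped.  Hits are sorted by (guide_id, chrom, start, strand).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    guides = list(guides)
    hits: list[OfftargetHit] = []
    if not guides:
        return hits

    seg_cache: dict[int, list[tuple[int, int]]] = {}
    lengths_needed: set[int] = set()
    for g in guides:
        L = len(g.guide)
        if L not in seg_cache:
            seg_cache[L] = _segments(L, k)
            lengths_needed.update(length for _, length in seg_cache[L])

    for chrom, rec in genome.chromosomes.items():
        clen = len(rec)
        for strand, seq in (("+", rec.seq), ("-", revcomp(rec.seq))):
            index = _qgram_index(seq, lengths_needed)
            for g in guides:
                L = len(g.guide)
                w = L + 3
                if clen < w:
                    continue
                candidates: set[int] = set()
                for off, length in seg_cache[L]:
                    for occ in index[length].get(g.guide[off : off + length], ()):
                        p = occ - off
                        if 0 <= p <= clen - w:
                            candidates.add(p)
                for p in sorted(candidates):
                    verified = _verify_window(seq[p : p + w], g.guide)
                    if verified is not None and len(verified[0]) <= k:
                        hits.append(_emit(g.guide_id, chrom, clen, p, strand, w, verified))
    hits.sort(key=OfftargetHit.key)
    return hits


def brute_force_scan(guide, genome: Genome, k: int = 5) -> list[OfftargetHit]:
    """Naive O(genome x L) per-window scan; the oracle for the indexed engine.

    Deliberately shares no candidate generation or verification code with
    :func:`search_offtargets`: every window on both strands is checked from
    first principles.
    """
    guide_seq = guide.guide
    guide_id = guide.guide_id
    L = len(guide_seq)
    w = L + 3
    hits: list[OfftargetHit] = []
    for chrom, rec in genome.chromosomes.items():
        clen = len(rec)
        if clen < w:
            continue
        for strand, seq in (("+", rec.seq), ("-", revcomp(rec.seq))):
            for p in range(clen - w + 1):
                pam23 = seq[p + L + 1 : p + L + 3]
                if pam23 == "GG":
                    pam_class = "NGG"
                elif pam23 == "AG":
                    pam_class = "NAG"
                else:
                    continue
                mm = []
                for j in range(L):
                    b = seq[p + j]
                    if b != guide_seq[j] or b == "N":
                        mm.append(L - j)
                        if len(mm) > k:
                            break
                if len(mm) > k:
                    continue
                rendered = "".join(
                    seq[p + j].lower() if (L - j) in mm else seq[p + j]
                    for j in range(L)
                ) + seq[p + L : p + L + 3]
                if strand == "+":
                    start, end = p + 1, p + w
                else:
                    start, end = clen - (p + w) + 1, clen - p
                hits.append(
                    OfftargetHit(
                        guide_id=guide_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        site_seq=rendered,
                        mismatch_positions=frozenset(mm),
                        n_mismatch=len(mm),
                        pam_class=pam_class,
                    )
                )
    hits.sort(key=OfftargetHit.key)
    return hits


def count_offtargets(hits, guide_id: str) -> int:
    """Total hit count for one guide, including perfect on-target matches."""
    return sum(1 for h in hits if h.guide_id == guide_id)
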
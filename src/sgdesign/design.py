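"""Guide QC, cloning-oligo generation and validation-amplicon extraction.

Guides destined for a U6/T7-driven sgRNA expression vector must avoid
homopolymer and short tandem repeats: a run of 5+ T acts as an RNA Pol III
terminator, runs of 6+ A/C/G and more than 6 tandem copies of a di- or
trinucleotide unit complicate synthesis and cloning.  Passing guides are
turned into a Golden-Gate-ready oligo duplex by prepending a 4-nt BsaI
adapter (lowercase) to the guide (sense oligo) and to its reverse
complement (antisense oligo); defaults 'accg'/'aaac' fit a pGL3-U6 style
vector.  For T7E1-assay validation, an amplicon window (default 1000 bp)
is extracted around the predicted cleavage point, which lies 3 nt upstream
of the PAM.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .seqcore import DnaSequence, Genome, revcomp

__all__ = [
    "OligoPair",
    "FlankRequest",
    "OligoDesignError",
    "qc_guide",
    "make_oligos",
    "extract_flank",
    "cleavage_center",
]

log = logging.getLogger(__name__)

_POLY_T = re.compile(r"T{5,}")
_POLY_ACG = re.compile(r"A{6,}|C{6,}|G{6,}")
_DI_REPEAT = re.compile(r"([ACGT]{2})\1{6,}")  # >6 tandem copies of a 2-nt unit
_TRI_REPEAT = re.compile(r"([ACGT]{3})\1{6,}")  # >6 tandem copies of a 3-nt unit


class OligoDesignError(ValueError):
    pass


def qc_guide(guide: str) -> str | None:
    """Repeat-sequence QC for an expression-vector guide.

    Returns None when the guide passes, otherwise a human-readable failure
    reason.  Rules: >=5 consecutive T; >=6 consecutive A, C or G; more
    than 6 tandem copies of any di- or trinucleotide unit.
    """
    m = _POLY_T.search(guide)
    if m:
        return f"poly-T run of {len(m.group())} (RNA Pol III terminator)"
    m = _POLY_ACG.search(guide)
    if m:
        return f"homopolymer run of {len(m.group())} {m.group()[0]}"
    m = _DI_REPEAT.search(guide)
    if m:
        return f"dinucleotide unit {m.group(1)} repeated >6 times"
    m = _TRI_REPEAT.search(guide)
    if m:
        return f"trinucleotide unit {m.group(1)} repeated >6 times"
    return None


@dataclass(frozen=True)
class OligoPair:
    """Annealing-ready oligo duplex for one guide (adapters lowercase)."""

    guide_id: str
    sense_oligo: str
    antisense_oligo: str
    adapter_sense: str
    adapter_antisense: str


def make_oligos(
    guide: str,
    guide_id: str = "",
    adapters: tuple[str, str] = ("accg", "aaac"),
    promoter: str = "U6",
) -> OligoPair:
    """Build the sense/antisense cloning oligos for one guide.

    Refuses guides that fail :func:`qc_guide`.  Guides not starting with G
    under a U6/T7 promoter get a warning (transcript initiation), not an
    error.
    """
    reason = qc_guide(guide)
    if reason is not None:
        raise OligoDesignError(f"guide {guide_id or guide} fails QC: {reason}")
    if promoter in ("U6", "T7") and not guide.startswith("G"):
        log.warning(
            "guide %s does not start with G; %s-driven transcription may "
            "initiate poorly",
            guide_id or guide,
            promoter,
        )
    ad_s, ad_a = adapters
    return OligoPair(
        guide_id=guide_id,
        sense_oligo=ad_s.lower() + guide,
        antisense_oligo=ad_a.lower() + revcomp(guide),
        adapter_sense=ad_s.lower(),
        adapter_antisense=ad_a.lower(),
    )


@dataclass(frozen=True)
class FlankRequest:
    """A window of ``window`` bp centered on a cleavage position."""

    chrom: str
    cleavage_center: int
    window: int = 1000

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


def cleavage_center(start: int, end: int, strand: str, guide_len: int | None = None) -> int:
    """Sense-strand position of the blunt cut, 3 nt upstream of the PAM.

    ``start``/``end`` delimit the full guide+PAM window (1-based closed);
    for a '+'/'S' site the PAM occupies the last 3 bases, for a '-'/'A'
    site the first 3 (on the sense strand).
    """
    del guide_len  # the cut is PAM-anchored, independent of guide length
    if strand in ("+", "S"):
        return end - 5  # 3rd guide base upstream of the PAM
    return start + 5


def extract_flank(genome: Genome, request: FlankRequest) -> DnaSequence:
    """Extract the amplicon window around a cleavage center.

    The window is centered with ``(window-1)//2`` bases to the left of the
    center (for even windows the center sits just left of the midpoint) and
    clamped at the chromosome bounds, so the returned fragment may be
    shorter than requested near ends.  The record id carries the 1-based
    closed coordinates, e.g. ``chr1:101-1100``.
    """
    if request.chrom not in genome:
        raise KeyError(f"unknown chromosome {request.chrom!r}")
    clen = genome.lengths[request.chrom]
    c = request.cleavage_center
    if not (1 <= c <= clen):
        raise ValueError(
            f"cleavage center {c} outside chromosome {request.chrom!r} (length {clen})"
        )
    start = c - (request.window - 1) // 2
    end = start + request.window - 1
    start_c, end_c = max(1, start), min(clen, end)
    if (start_c, end_c) != (start, end):
        log.warning(
            "flank window at %s:%d clamped to [%d, %d]",
            request.chrom,
            c,
            start_c,
            end_c,
        )
    return DnaSequence(
        id=f"{request.chrom}:{start_c}-{end_c}",
        seq=genome.fetch(request.chrom, start_c, end_c),
    )
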
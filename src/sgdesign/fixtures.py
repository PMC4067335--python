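"""Synthetic toy genomes with planted on-/off-target sites.

Every stage of the pipeline can be tested without downloads: a uniform
random ACGT background is generated and guide+PAM windows are written at
chosen coordinates, with chosen mismatch positions (PAM-proximal = 1) and
PAM trinucleotides, on either strand.  The returned truth table records,
for each planted copy, the coordinates and the expected mismatch count,
PAM class and POT type — the background may add further genuine hits, so
the guarantee is planted ⊆ found.

The RNG is numpy's default PCG64 generator seeded explicitly, so a fixed
seed reproduces the genome byte-for-byte across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import DnaSequence, Genome, revcomp

__all__ = ["PlantCopy", "PlantSpec", "TruthRecord", "make_toy_genome"]

_BASES = np.array(list("ACGT"))
# deterministic substitution used to realize a planted mismatch
_MUTATE = {"A": "C", "C": "G", "G": "T", "T": "A"}

@dataclass(frozen=True)
class PlantCopy:
    """One genomic copy of a guide-derived site."""

    chrom: str
    position: int  # 1-based start of the guide+PAM window on the sense strand
    strand: str  # "+" or "-"
    mismatch_positions: frozenset = frozenset()  # PAM-proximal = 1
    pam: str = "AGG"


@dataclass(frozen=True)
class PlantSpec:
    guide: str
    copies: tuple = ()


@dataclass(frozen=True)
class TruthRecord:
    """Expected engine/classifier outcome for one planted copy."""

    guide: str
    chrom: str
    start: int
    end: int
    strand: str
    n_mismatch: int
    pam_class: str | None  # None when the planted PAM is intolerable
    expected_type: str | None  # "perfect" | "I" | "II" | "III" | "excluded" | None


def _expected_type(mm: frozenset, n: int, pam_class: str | None) -> str | None:
    """Independent restatement of the POT typing rule, for truth tables only."""
    if pam_class is None:
        return None  # site is never emitted
    if n == 0:
        return "perfect" if pam_class == "NGG" else "I"
    in_I = any(1 <= p <= 7 for p in mm)
    in_II = any(8 <= p <= 12 for p in mm)
    if in_I:
        return "III" if n <= 3 else "excluded"
    if n > 5:
        return "excluded"
    return "II" if in_II else "I"


def _site_sequence(guide: str, mm: frozenset, pam: str) -> str:
    """The guide+PAM string actually written into the genome (hit-strand 5'->3')."""
    L = len(guide)
    bases = list(guide)
    for p in mm:
        if not 1 <= p <= L:
            raise ValueError(f"planted mismatch position {p} outside 1..{L}")
        j = L - p
        bases[j] = _MUTATE[bases[j]]
    return "".join(bases) + pam


def make_toy_genome(
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 5000,
    plants: tuple = (),
) -> tuple[Genome, list[TruthRecord]]:
    """Random background genome with planted sites and their truth table.

    Chromosomes are named ``chr1..chrN``.  Planted windows must not collide
    with each other and must lie within their chromosome; violations raise
    ValueError.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": list("".join(rng.choice(_BASES, size=chrom_len)))
        for i in range(n_chrom)
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chroms}
    truth: list[TruthRecord] = []

    for spec in plants:
        L = len(spec.guide)
        w = L + 3
        for copy in spec.copies:
            if copy.chrom not in chroms:
                raise ValueError(f"unknown chromosome {copy.chrom!r} in plant")
            start, end = copy.position, copy.position + w - 1
            if start < 1 or end > chrom_len:
                raise ValueError(
                    f"planted window [{start}, {end}] outside {copy.chrom} "
                    f"(length {chrom_len})"
                )
            for s0, e0 in occupied[copy.chrom]:
                if start <= e0 and s0 <= end:
                    raise ValueError(
                        f"planted window [{start}, {end}] on {copy.chrom} collides "
                        f"with [{s0}, {e0}]"
                    )
            occupied[copy.chrom].append((start, end))

            site = _site_sequence(spec.guide, copy.mismatch_positions, copy.pam)
            written = site if copy.strand == "+" else revcomp(site)
            chroms[copy.chrom][start - 1 : end] = list(written)

            pam23 = copy.pam[1:]
            pam_class = {"GG": "NGG", "AG": "NAG"}.get(pam23)
            n = len(copy.mismatch_positions)
            truth.append(
                TruthRecord(
                    guide=spec.guide,
                    chrom=copy.chrom,
                    start=start,
                    end=end,
                    strand=copy.strand,
                    n_mismatch=n,
                    pam_class=pam_class,
                    expected_type=_expected_type(
                        copy.mismatch_positions, n, pam_class
                    ),
                )
            )

    genome = Genome(
        chromosomes={
            name: DnaSequence(name, "".join(seq)) for name, seq in chroms.items()
        }
    )
    return genome, truth


def random_guide(rng: np.random.Generator, length: int = 20) -> str:
    """Uniform random ACGT guide sequence."""
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# Canned end-to-end scenario: a synthetic 5-guide gene whose planted genome
# copies exercise every branch of the selection cascade.

#: Guides with ~20-50% GC and no internal GG/CC dinucleotides, so the demo
#: input record contains exactly one protospacer per guide and none on the
#: antisense strand.
DEMO_GUIDES = {
    "specific": "GATCGATCGATCGATCGATC",  # perfect + one 3-mismatch POT -> kept
    "multi": "GACTGACTGACTGACTGACT",  # two perfect loci -> multi_locus
    "junction": "GTACGTACGTACGTACGTAC",  # absent from genome -> not_on_genome
    "risky": "GTCAGTCAGTCAGTCAGTCA",  # one 1-mismatch POT -> has_1or2_mm_pot
    "nag_twin": "GACGATATCGATATCGATAT",  # perfect + 0-mismatch NAG POT -> kept
}

#: verdict and discard reason predicted by the selection cascade, keyed by
#: the ordinal each guide receives in the demo record (scan order above).
DEMO_EXPECTED = {
    "toygene_S_1": ("kept", "none"),
    "toygene_S_2": ("discarded", "multi_locus"),
    "toygene_S_3": ("discarded", "not_on_genome"),
    "toygene_S_4": ("discarded", "has_1or2_mm_pot"),
    "toygene_S_5": ("kept", "none"),
}


def demo_pipeline_inputs(seed: int = 12345, chrom_len: int = 3000):
    """Input record, toy genome and truth table for an end-to-end run.

    The record carries five protospacers (AT/TA spacers keep the scan free
    of accidental sites); the genome plants perfect, mismatched, NAG-PAM,
    rejected-PAM and duplicated copies so the selection cascade discards
    exactly the guides named in :data:`DEMO_EXPECTED`.
    """
    g = DEMO_GUIDES
    seq = "AT" * 6
    for i, name in enumerate(g):
        seq += g[name] + "AGG" + ("TA" if i % 2 == 0 else "AT") * 6
    record = DnaSequence("toygene", seq)

    plants = (
        PlantSpec(g["specific"], (
            PlantCopy("chr1", 101, "+"),
            PlantCopy("chr1", 201, "+", frozenset({13, 15, 18})),
        )),
        PlantSpec(g["multi"], (
            PlantCopy("chr1", 301, "+", pam="TGG"),
            PlantCopy("chr2", 301, "+"),
        )),
        PlantSpec(g["risky"], (
            PlantCopy("chr1", 401, "+", pam="CGG"),
            PlantCopy("chr2", 501, "-", frozenset({15})),
        )),
        PlantSpec(g["nag_twin"], (
            PlantCopy("chr1", 501, "+", pam="GGG"),
            PlantCopy("chr2", 601, "+", pam="TAG"),
            PlantCopy("chr2", 701, "+", pam="TCG"),
        )),
    )
    genome, truth = make_toy_genome(seed, 2, chrom_len, plants)
    return record, genome, truth
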
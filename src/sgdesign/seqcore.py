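"""Sequence primitives and FASTA/genome I/O.

DNA is handled as plain uppercase strings over the alphabet {A, C, G, T, N}.
All coordinates exposed by this package are 1-based, fully closed intervals;
conversion from Python slices is centralized in :func:`Genome.fetch`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "DnaSequence",
    "Genome",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "format_genome",
    "revcomp",
    "gc_percent",
]

_VALID = re.compile(r"^[ACGTN]*$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Raised for malformed FASTA input (empty file, duplicate IDs, bad characters)."""


@dataclass(frozen=True)
class DnaSequence:
    """One named DNA sequence, normalized to uppercase {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence record has an empty id")
        if not _VALID.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise FastaError(
                f"record {self.id!r} contains characters outside ACGTN: {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _normalize(raw: str, record_id: str) -> str:
    """Uppercase, map RNA U->T, and validate the alphabet."""
    s = raw.upper().replace("U", "T")
    if not _VALID.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise FastaError(f"record {record_id!r} contains illegal characters: {bad}")
    return s


def read_fasta(path) -> list[DnaSequence]:
    """Read a multi-FASTA file into a list of :class:`DnaSequence`.

    Sequences are uppercased and U is mapped to T; characters outside
    {A,C,G,T,N} raise :class:`FastaError`, as do duplicate record IDs and
    files with no records.
    """
    records: list[DnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        records.append(DnaSequence(rec.id, _normalize(str(rec.seq), rec.id)))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write records (DnaSequence iterables) as FASTA."""
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")
    del width  # line width is delegated to Biopython's writer


@dataclass
class Genome:
    """An ordered collection of chromosomes with 1-based closed-interval access."""

    chromosomes: dict[str, DnaSequence] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self.chromosomes.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``chrom`` over the 1-based closed interval [start, end]."""
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.chromosomes[chrom].seq
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}] outside chromosome {chrom!r} (length {len(seq)})"
            )
        return seq[start - 1 : end]


def format_genome(path) -> Genome:
    """Load a genome multi-FASTA, keeping only chromosome names and sequence.

    Headers are truncated to their first whitespace-delimited token (so an
    Ensembl-style ``>1 dna:chromosome ...`` becomes chromosome ``1``) and
    soft-masked lowercase bases are uppercased; repeat masking is
    deliberately ignored so the off-target search stays genome-complete.
    """
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id  # Biopython's id is the first whitespace token
        if name in genome.chromosomes:
            raise FastaError(f"duplicate chromosome name {name!r} in {path}")
        genome.chromosomes[name] = DnaSequence(name, _normalize(str(rec.seq), name))
    if not genome.chromosomes:
        raise FastaError(f"no sequences found in genome file {path}")
    return genome


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content as a percentage; N counts in the denominator only."""
    if not seq:
        raise ValueError("gc_percent of an empty sequence is undefined")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
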
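"""GTF intersection: flag off-target/POT loci that fall in annotated features.

A cleavage event disrupts both strands, so overlap is strand-agnostic; any
>= 1 bp overlap between a hit window and a feature of interest (default
CDS, exon, gene) counts.  'chr1' vs '1' chromosome dialects are harmonized
by an optional prefix-strip rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "GtfFeature",
    "GtfParseError",
    "AnnotatedRecord",
    "read_gtf",
    "annotate_hits",
]

log = logging.getLogger(__name__)

DEFAULT_FEATURE_TYPES = frozenset({"CDS", "exon", "gene"})


class GtfParseError(ValueError):
    pass


@dataclass(frozen=True)
class GtfFeature:
    chrom: str
    source: str
    feature_type: str
    start: int  # 1-based closed
    end: int
    strand: str
    attributes: dict

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GtfParseError(
                f"feature {self.feature_type} on {self.chrom} has start > end"
            )


def read_gtf(path) -> list[GtfFeature]:
    """Parse a 9-column GTF file; malformed lines are reported with numbers."""
    features: list[GtfFeature] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                errors.append(f"line {lineno}: fewer than 9 tab-delimited columns")
                continue
            try:
                f = feature_from_line(line, dialect=None)
                features.append(
                    GtfFeature(
                        chrom=f.seqid,
                        source=f.source,
                        feature_type=f.featuretype,
                        start=f.start,
                        end=f.end,
                        strand=f.strand,
                        attributes={k: v[0] if v else "" for k, v in f.attributes.items()},
                    )
                )
            except Exception as exc:  # gffutils raises assorted types
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise GtfParseError(
            f"{len(errors)} malformed GTF line(s) in {path}: " + "; ".join(errors[:5])
        )
    return features


@dataclass(frozen=True)
class AnnotatedRecord:
    """A hit (or POT record) with its overlapping features; [] = intergenic."""

    record: object
    overlaps: tuple  # of (feature_type, gene_id, gene_name)

    @property
    def label(self) -> str:
        return "genic" if self.overlaps else "intergenic"


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def _hit_of(record):
    """Accept either OfftargetHit-like objects or PotRecord wrappers."""
    return record.hit if hasattr(record, "hit") else record


def annotate_hits(
    hits,
    features: list[GtfFeature],
    types_of_interest=DEFAULT_FEATURE_TYPES,
    harmonize_chrom_names: bool = True,
) -> list[AnnotatedRecord]:
    """Attach overlapping features to each hit (>= 1 bp overlap rule).

    Output order follows input order; the result does not depend on the
    order of ``features``.  If the hits and features share no chromosome
    name at all a warning is logged, not raised.
    """
    norm = _strip_chr if harmonize_chrom_names else (lambda s: s)
    trees: dict[str, IntervalTree] = {}
    for f in features:
        if types_of_interest and f.feature_type not in types_of_interest:
            continue
        # intervaltree is half-open; +1 converts the closed GTF end
        trees.setdefault(norm(f.chrom), IntervalTree())[f.start : f.end + 1] = f

    hits = list(hits)
    hit_chroms = {norm(_hit_of(h).chrom) for h in hits}
    if hits and trees and not (hit_chroms & set(trees)):
        log.warning(
            "no chromosome names shared between hits (%s) and GTF features (%s)",
            sorted(hit_chroms)[:5],
            sorted(trees)[:5],
        )

    out: list[AnnotatedRecord] = []
    for record in hits:
        h = _hit_of(record)
        tree = trees.get(norm(h.chrom))
        overlaps = []
        if tree is not None:
            for iv in sorted(tree[h.start : h.end + 1]):
                f = iv.data
                overlaps.append(
                    (
                        f.feature_type,
                        f.attributes.get("gene_id", ""),
                        f.attributes.get("gene_name", ""),
                    )
                )
        out.append(AnnotatedRecord(record=record, overlaps=tuple(overlaps)))
    return out
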
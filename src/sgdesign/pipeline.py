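"""End-to-end sgRNA design pipeline.

Four stages: (1) protospacer search on the input records, (2) genome-wide
off-target enumeration, (3) POT classification and the selection cascade,
(4) oligo design and validation-amplicon extraction, with optional GTF
annotation of the POT loci.  All reports are tab-delimited text inside one
output directory (report_protospacer_single.txt /
report_protospacer_pairs.txt, search_OT.txt, Type_I/II/III_POT,
Sort_POT_byID, Final_report).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import annotate as annotate_mod
from .design import FlankRequest, OligoDesignError, cleavage_center, extract_flank, make_oligos
from .offtarget import search_offtargets
from .pot import (
    RegionScheme,
    build_reports,
    classify_all,
    select_guides,
    write_pot_reports,
)
from .seqcore import format_genome, read_fasta, write_fasta
from .target_search import find_pairs, find_protospacers

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("sgdesign")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the tool's classic settings
    (20-nt guides, GC 20-80%, up to 5 mismatches, nickase offset -2..32)."""

    input_path: str = ""
    genome_path: str = ""
    gtf_path: str | None = None
    guide_len: int = 20
    gc_min: float = 20.0
    gc_max: float = 80.0
    strand_mode: str = "b"  # s | a | b
    design_type: str = "s"  # s(ingle) | p(aired)
    max_mismatch: int = 5
    offset_min: int = -2
    offset_max: int = 32
    pattern: str = "X20"
    output_dir: str = "sgdesign_out"
    adapters: tuple[str, str] = ("accg", "aaac")
    flank_window: int = 1000
    seed: int | None = None
    annotate_types: frozenset = field(
        default_factory=lambda: annotate_mod.DEFAULT_FEATURE_TYPES
    )

    def validate(self) -> None:
        if not self.input_path or not self.genome_path:
            raise ValueError("input_path and genome_path are required")
        if self.gc_min > self.gc_max:
            raise ValueError(f"gc_min ({self.gc_min}) > gc_max ({self.gc_max})")
        if self.offset_min > self.offset_max:
            raise ValueError(
                f"offset_min ({self.offset_min}) > offset_max ({self.offset_max})"
            )
        if self.strand_mode not in ("s", "a", "b"):
            raise ValueError(f"strand_mode must be s/a/b, got {self.strand_mode!r}")
        if self.design_type not in ("s", "p"):
            raise ValueError(f"design_type must be s/p, got {self.design_type!r}")


def _protospacer_frame(sites) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "guide_id": p.guide_id,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "sequence": p.site,
                "pattern": p.pattern,
                "gc_percent": round(p.gc, 1),
            }
            for p in sites
        ],
        columns=["guide_id", "start", "end", "strand", "sequence", "pattern", "gc_percent"],
    )


def _pairs_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "left_guide_id": gp.left.guide_id,
                "left_sequence": gp.left.site,
                "left_start": gp.left.start,
                "left_end": gp.left.end,
                "right_guide_id": gp.right.guide_id,
                "right_sequence": gp.right.site,
                "right_start": gp.right.start,
                "right_end": gp.right.end,
                "offset": gp.offset,
            }
            for gp in pairs
        ],
        columns=[
            "left_guide_id", "left_sequence", "left_start", "left_end",
            "right_guide_id", "right_sequence", "right_start", "right_end",
            "offset",
        ],
    )


def _hits_frame(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_seq": h.site_seq,
                "n_mismatch": h.n_mismatch,
                "guide_id": h.guide_id,
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "pam_class": h.pam_class,
            }
            for h in hits
        ],
        columns=["site_seq", "n_mismatch", "guide_id", "chrom", "start", "end",
                 "strand", "pam_class"],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a summary dict of per-stage objects and counts.

    Inputs are validated before any output is written, so a bad input never
    leaves a partial output tree behind.
    """
    config.validate()

    # ---- stage: load inputs (before creating any output) ----
    try:
        records = read_fasta(config.input_path)
        genome = format_genome(config.genome_path)
        features = (
            annotate_mod.read_gtf(config.gtf_path) if config.gtf_path else None
        )
    except Exception as exc:
        raise PipelineError("load_inputs", exc) from exc

    os.makedirs(config.output_dir, exist_ok=True)
    fh = logging.FileHandler(os.path.join(config.output_dir, "run.log"))
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("sgdesign")
    root.addHandler(fh)
    try:
        return _run_stages(config, records, genome, features)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run_stages(config, records, genome, features) -> dict:
    out = config.output_dir
    log.info(
        "loaded %d input record(s), genome of %d chromosome(s)",
        len(records),
        len(genome.chromosomes),
    )

    # ---- stage: protospacer search ----
    try:
        sites, pairs = [], []
        for rec in records:
            sites.extend(
                find_protospacers(
                    rec, config.strand_mode, config.pattern, config.guide_len,
                    config.gc_min, config.gc_max,
                )
            )
            if config.design_type == "p":
                pairs.extend(
                    find_pairs(
                        rec, config.pattern, config.guide_len, config.gc_min,
                        config.gc_max, config.offset_min, config.offset_max,
                    )
                )
        _protospacer_frame(sites).to_csv(
            os.path.join(out, "report_protospacer_single.txt"), sep="\t", index=False
        )
        if config.design_type == "p":
            _pairs_frame(pairs).to_csv(
                os.path.join(out, "report_protospacer_pairs.txt"), sep="\t", index=False
            )
        log.info("found %d protospacer(s), %d pair(s)", len(sites), len(pairs))
    except Exception as exc:
        raise PipelineError("target_search", exc) from exc

    # ---- stage: off-target search ----
    try:
        hits = search_offtargets(sites, genome, config.max_mismatch)
        _hits_frame(hits).to_csv(
            os.path.join(out, "search_OT.txt"), sep="\t", index=False
        )
        log.info("off-target search: %d hit(s) for %d guide(s)", len(hits), len(sites))
    except Exception as exc:
        raise PipelineError("offtarget_search", exc) from exc

    # ---- stage: classification and selection ----
    try:
        scheme = RegionScheme(config.guide_len)
        pot_records = classify_all(hits, scheme)
        reports = select_guides(build_reports(sites, pot_records))
        write_pot_reports(pot_records, out, reports)
        kept = [r for r in reports if r.verdict == "kept"]
        log.info(
            "selection: %d guide(s) kept of %d (discards: %s)",
            len(kept),
            len(reports),
            {r.guide_id: r.discard_reason for r in reports if r.verdict == "discarded"},
        )
    except Exception as exc:
        raise PipelineError("classification", exc) from exc

    # ---- stage: oligo design + flank extraction for kept guides ----
    try:
        site_by_id = {p.guide_id: p for p in sites}
        perfect_by_id = {}
        for h in hits:
            if h.n_mismatch == 0 and h.pam_class == "NGG":
                perfect_by_id.setdefault(h.guide_id, h)
        oligo_rows, flanks, n_qc_fail = [], [], 0
        for rep in kept:
            p = site_by_id[rep.guide_id]
            try:
                pair = make_oligos(p.guide, p.guide_id, config.adapters)
            except OligoDesignError as exc:
                n_qc_fail += 1
                log.warning("%s", exc)
                continue
            oligo_rows.append(
                {
                    "guide_id": pair.guide_id,
                    "sense_oligo": pair.sense_oligo,
                    "antisense_oligo": pair.antisense_oligo,
                }
            )
            on_target = perfect_by_id.get(rep.guide_id)
            if on_target is not None:
                center = cleavage_center(
                    on_target.start, on_target.end, on_target.strand
                )
                flank = extract_flank(
                    genome,
                    FlankRequest(on_target.chrom, center, config.flank_window),
                )
                flanks.append(
                    type(flank)(id=f"{rep.guide_id}|{flank.id}", seq=flank.seq)
                )
        pd.DataFrame(
            oligo_rows, columns=["guide_id", "sense_oligo", "antisense_oligo"]
        ).to_csv(os.path.join(out, "oligos.txt"), sep="\t", index=False)
        if flanks:
            write_fasta(flanks, os.path.join(out, "flanks.fa"))
        log.info(
            "designed oligos for %d guide(s); %d failed repeat QC", len(oligo_rows),
            n_qc_fail,
        )
    except Exception as exc:
        raise PipelineError("design_tools", exc) from exc

    # ---- stage: optional annotation ----
    annotated = None
    if features is not None:
        try:
            pots = [r for r in pot_records if r.is_pot]
            annotated = annotate_mod.annotate_hits(pots, features, config.annotate_types)
            rows = [
                {
                    "guide_id": a.record.hit.guide_id,
                    "chrom": a.record.hit.chrom,
                    "start": a.record.hit.start,
                    "end": a.record.hit.end,
                    "pot_type": a.record.pot_type,
                    "label": a.label,
                    "features": ";".join(
                        f"{t}:{gid}" + (f"({name})" if name else "")
                        for t, gid, name in a.overlaps
                    ),
                }
                for a in annotated
            ]
            pd.DataFrame(
                rows,
                columns=["guide_id", "chrom", "start", "end", "pot_type", "label",
                         "features"],
            ).to_csv(os.path.join(out, "POT_annotation.txt"), sep="\t", index=False)
            log.info(
                "annotation: %d/%d POT in annotated features",
                sum(1 for a in annotated if a.overlaps), len(annotated),
            )
        except Exception as exc:
            raise PipelineError("annotate", exc) from exc

    return {
        "records": records,
        "genome": genome,
        "sites": sites,
        "pairs": pairs,
        "hits": hits,
        "pot_records": pot_records,
        "reports": reports,
        "kept": kept,
        "annotated": annotated,
    }
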
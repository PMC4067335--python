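# Methods

## Model and assumptions

The package treats Cas9 target recognition as exact string matching with a
bounded mismatch budget. A target site is an L-nt protospacer followed by a
3-nt PAM; cleavage competence is assumed whenever (i) the PAM reads NGG, or
NAG with reduced activity, on the protospacer strand and (ii) the guide:
protospacer Hamming distance is at most k. No probabilistic cleavage score
(CFD/MIT-style) is computed: the output is a classification, not a cleavage
probability. Indels/bulges between guide and protospacer are out of scope,
as are non-SpCas9 PAMs.

Mismatch *position* carries the biology. Positions are numbered from the
PAM-proximal base (position 1) outward, because proximal mismatches
suppress cleavage most strongly. Region I is positions 1–7 (the
recognition-critical core), region II is 8–12 (the rest of the 12-nt
seed), region III is 13–L (non-seed). The three POT types follow from
that geometry:

| type | mismatches | placement |
|------|-----------|-----------|
| I    | 1–5       | all in region III (seed identical) |
| II   | 1–5       | in II∪III, ≥1 in region II, none in I |
| III  | 1–3       | ≥1 in region I |

These definitions partition every mismatch set of size 1–5 (verified
exhaustively over all 21 700 subsets of positions 1–20 of size ≤5 in the
test suite) once two boundary cases are fixed:

* **0 mismatches, NGG** — a perfect-match locus. Not a POT; it feeds the
  multi-locus discard instead.
* **0 mismatches, NAG** — classified Type I with n = 0 and given the top
  risk rank. A perfect protospacer next to the tolerated PAM is the most
  cleavable non-canonical site, and it is the only way a 0-mismatch POT
  can arise.
* **region-I mismatch with n ∈ {4,5}** — fits no type; excluded from the
  POT set but still counted in the raw off-target total.

Risk ranking is an ordinal scale only: Type I ranks 1–6 (n = 0..5), Type
II 7–11 (n = 1..5), Type III 12–14 (n = 1..3). Equal (type, n) ties are
equal ranks; only the order is meaningful.

## Parameters

| parameter | default | unit | rationale |
|-----------|---------|------|-----------|
| guide length L | 20 | nt | standard SpCas9 spacer; 17–18 supported for truncated high-specificity guides |
| pattern | X20 | — | the least restrictive 5′ pattern; GX19/GGX18 enforce the U6/T7 G start |
| GC window | 20–80 | % | guides outside this range cleave poorly; bounds inclusive, computed on the guide only (PAM excluded) |
| max mismatches k | 5 | — | off-target mutations have been observed at 5-mismatch sites |
| pair offset | −2 to 32 | bp | the empirically efficient window for D10A double nicking, PAM-out |
| flank window | 1000 | bp | amplicon length for T7E1/sequencing validation |
| adapters | accg / aaac | — | BsaI Golden-Gate overhangs for a pGL3-U6-style vector |

The pair offset is defined, with both guides projected onto sense-strand
coordinates, as `(sense guide start) − (antisense guide end) − 1`: the
signed gap between the two PAM-distal ends. Abutting guides give 0,
overlapping guides negative values. Pairing is restricted to PAM-out
orientation (antisense member leftmost), the configuration that produces
5′ overhangs under double nicking.

## Numerical and procedural choices

* **Coordinates** are 1-based fully closed everywhere a user sees them;
  the only slice conversion lives in `Genome.fetch`.
* **Engine.** Pigeonhole partition: the guide splits into k+1 contiguous
  segments (lengths differing by ≤1), so a window within k mismatches
  matches ≥1 segment exactly; exact occurrences come from a q-gram
  position index built once per chromosome orientation, and candidates are
  verified by full Hamming comparison plus the PAM rule. The scheme is
  lossless for ≤k mismatches. A deliberately independent naive per-window
  scan is kept as the test oracle.
* **N bases.** Genome N never matches any guide base (it counts as a
  mismatch); a literal N at PAM positions 2–3 disqualifies the window;
  the PAM's first position is never compared. Guides containing N are
  dropped at search time (logged) — they cannot be synthesized. Ambiguity
  codes other than N are rejected on input rather than expanded.
* **Soft masking** is uppercased and otherwise ignored so the off-target
  search is genome-complete; windows overhanging chromosome ends are
  skipped, not padded.
* **Repeat QC** (cloning): fail on ≥5 consecutive T (Pol III terminator),
  ≥6 consecutive A/C/G, or more than 6 tandem copies of a di-/tri-
  nucleotide unit (counted as copies, not bases; the trinucleotide rule
  cannot trigger inside a 20-nt guide and is retained for longer inputs).
  "Fewer than required" boundary cases (4 T, 5 A, 6 copies) pass.
* **Amplicon centering.** The cut site is taken 3 nt upstream of the PAM.
  For an even window w the center sits just left of the midpoint
  (start = center − (w−1)//2); windows are clamped (never shifted) at
  chromosome ends, so fragments near ends may be short. Stated so
  extraction is bit-reproducible.
* **Selection order** is fixed: not_on_genome, then multi_locus, then
  has_1or2_mm_pot; a guide hit by several rules reports the first. The
  1–2-mismatch discard reads the rule literally (n_mismatch ∈ {1,2}):
  a 0-mismatch NAG POT does *not* trigger it, though it is ranked as the
  most dangerous POT and is plainly visible in the per-guide report.
* **On-target identification.** When the input is mRNA/CDS (genomic
  coordinates unknown), the single perfect NGG hit is deemed the
  on-target; perfect hits are counted in `n_perfect` and never classified
  as POT.
* **Annotation overlap** is strand-agnostic (cleavage disrupts both
  strands) with a ≥1 bp rule; 'chr' prefixes are stripped on both sides by
  default to reconcile Ensembl and UCSC naming. Default feature types:
  CDS, exon, gene.

## Synthetic data

`sgdesign.fixtures` generates uniform-random ACGT backgrounds (numpy PCG64,
explicit seed, byte-reproducible) and writes guide-derived windows at
chosen coordinates: chosen mismatch positions (realized by a fixed cyclic
base substitution), chosen PAM, either strand. The truth table carries the
expected mismatch count, PAM class and POT type per copy; because the
background can legitimately contain further matching windows, the
guaranteed relation is planted ⊆ found, and equality assertions in tests
are guarded by an independent brute-force scan of the fixture.

What the toy genomes emulate: local sequence matching under the PAM and
mismatch rules, on both strands, at any chosen multiplicity. What they do
not emulate: repeat structure and segmental duplication (which dominate
real off-target counts), GC heterogeneity and chromatin context.
Consequently, passing tests demonstrate the correctness of the search,
classification and selection logic — not the field realism of off-target
*counts*, which on a real 3-Gb genome run into the hundreds or thousands
per guide.

Problem sizes used in the verification suite: toy genomes of 0.5–6 kb
across 1–2 chromosomes (100 random engine-vs-oracle instances, plus
randomized recovery scenarios), 50 random records of 100–800 bp for the
strand-decomposition identity, and the exhaustive 21 700-subset
classification enumeration. The full pipeline demo uses a 5-guide
synthetic gene against a 2 × 3 kb genome; the same code paths scale to
full mammalian genomes, where the off-target stage dominates runtime.

## Known limitations

* No on-target efficiency scoring and no probabilistic off-target score;
  the POT classes are ordinal categories.
* DNA/RNA-bulge off-targets and alternative PAMs are not modeled.
* The GTF intersection reports feature overlap only; it does not reason
  about promoters or regulatory regions.
* The whole-genome human benchmark requires the external genome FASTA; it
  is supported but not exercised by the bundled test data.
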
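# sgdesign

Design CRISPR/Cas9 single-guide RNAs (sgRNAs) against any genome, with an
exhaustive genome-wide enumeration of potential off-target cleavage sites
(POT), a seed-region mismatch classification of those sites, and automated
selection of high-specificity guides — plus the bench-facing extras: cloning
oligos for a U6/T7 sgRNA expression vector and amplicon windows for
validating cleavage by the T7E1 assay.

It is a local, genome-agnostic command-line tool and Python library for
molecular biologists and genome engineers who need specificity-screened
guides without uploading sequences to a web service.

## The method

**Target search.** A protospacer is an L-nt guide (default L = 20) followed
by an NGG PAM. Candidate sites are found under one of three 5′ patterns —
5′-GGX₁₈-NGG-3′, 5′-GX₁₉-NGG-3′ or 5′-X₂₀-NGG-3′ (G-prefixed patterns
guarantee the G start that U6/T7 transcription prefers) — on the sense
strand, the antisense strand, or both, with a guide GC% filter (default
20–80%). A paired mode enumerates PAM-out guide pairs for D10A-nickase
double nicking, constrained by the sgRNA offset: the signed distance in bp
between the PAM-distal (5′) ends of the two guides (default −2 to 32).

**Off-target enumeration.** Each guide+PAM (L+3 nt) is matched against
every window of both genome strands allowing up to k mismatches in the
guide (default k = 5). PAM handling: the N position is never compared; NGG
and the tolerated NAG are accepted, with the G→A change not counted as a
mismatch; NCG/NTG/NGA/NGT/NGC windows are discarded. The engine uses a
lossless pigeonhole seed index (guide split into k+1 segments; any window
within k mismatches must match one segment exactly) and is verified in the
test suite against a naive per-window oracle.

**POT classification.** Counting from the PAM-proximal base, the guide
splits into region I (positions 1–7), region II (8–12) and region III
(13–L); I+II form the seed. Off-target sites become
**Type I** (1–5 mismatches, all in region III), **Type II** (1–5
mismatches in II∪III, at least one in II) or **Type III** (1–3 mismatches,
at least one in region I); a region-I mismatch with 4–5 total fits no type
and is excluded from the POT set. Risk ranks order Type I > II > III and,
within a type, fewer mismatches as more dangerous.

**Selection.** Guides are discarded when they have no perfect genomic
match (e.g. exon-junction guides), match multiple loci perfectly, or carry
any POT with 1–2 mismatches; survivors are ranked by POT count, then total
off-target count.

## Worked example

The package ships a synthetic demo: a five-guide toy gene and a two-
chromosome toy genome with planted perfect, mismatched, NAG-PAM,
rejected-PAM and duplicated copies (`sgdesign.fixtures.demo_pipeline_inputs`).

```python
from sgdesign.fixtures import demo_pipeline_inputs
from sgdesign.seqcore import write_fasta
rec, genome, truth = demo_pipeline_inputs()
write_fasta([rec], "targets.fa")
write_fasta(genome.chromosomes.values(), "genome.fa")
```

```
$ sgdesign -i targets.fa -g genome.fa -d demo_out
INFO loaded 1 input record(s), genome of 2 chromosome(s)
INFO found 5 protospacer(s), 0 pair(s)
INFO off-target search: 11 hit(s) for 5 guide(s)
INFO selection: 2 guide(s) kept of 5 (discards: {'toygene_S_2': 'multi_locus',
  'toygene_S_3': 'not_on_genome', 'toygene_S_4': 'has_1or2_mm_pot'})
INFO designed oligos for 2 guide(s); 0 failed repeat QC
done: 5 protospacers, 11 off-target hits, 2 guides kept -> demo_out
```

Of the five candidate guides, one maps to two perfect loci (`multi_locus`),
one is absent from the genome (`not_on_genome`), and one has a 1-mismatch
off-target (`has_1or2_mm_pot`); the two survivors appear in
`demo_out/Final_report/final_report.txt`:

```
guide_id     total_ot  n_perfect  pot_I  pot_II  pot_III  pot_total
toygene_S_5  3         1          1      0       0        1
toygene_S_1  4         1          1      0       1        2
```

`toygene_S_5` sorts first: one POT (a 0-mismatch site next to a tolerated
NAG PAM, the top risk rank) versus two for `toygene_S_1`. Per-guide POT
detail lives in `demo_out/Sort_POT_byID/` with mismatched bases in
lowercase, e.g. `GAaCGcTgGATCGATCGATCAGG` (Type I, 3 mismatches, all
PAM-distal). `demo_out/oligos.txt` holds the annealing-ready duplexes
(`accg` + guide / `aaac` + reverse complement) and `demo_out/flanks.fa`
the ≤1000-bp validation amplicons centered on the cut site 3 nt upstream
of each PAM.

The CLI mirrors the classic single-letter grammar
(`-i -g -x -l -m -o -t -n -s -e`), e.g. a paired-nickase run with a custom
offset window: `sgdesign -i targets.fa -g genome.fa -o b -t p -s 5 -e 35`.
Add `--gtf annotation.gtf` to flag POT falling in CDS/exon/gene features.

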
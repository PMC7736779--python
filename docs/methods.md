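# Methods

## Coordinate model

All internal coordinates are 0-based, half-open intervals on named
sequences. External formats that count from 1 inclusively (the
show-coords alignment dialect, GFF3) are converted at the I/O boundary
and converted back on write; BED is already half-open. A single
arithmetic convention removes the usual off-by-one drift between
stages. Interval merging uses the separation `next.start − prev.end`,
so bookended intervals (separation 0) always merge — the semantics of
`bedtools merge -d`.

## Misassembled-inversion detection

A whole-genome alignment between two assemblies of the same genotype
renders a genuinely mis-oriented region as a cloud of small inverted
blocks. Detection is a fixed ladder over the reference-side intervals
of inverted blocks only, after a block-level filter at ≥ 98 % identity
and ≥ 1 kb aligned reference span:

1. merge at separation ≤ 100 kb,
2. keep merged intervals strictly > 100 kb,
3. merge survivors at ≤ 300 kb,
4. keep strictly > 700 kb,
5. merge survivors at ≤ 1 Mb.

Size filters are strict and merges inclusive, mirroring the printed
inequalities of the procedure this reimplements. Merging never crosses
sequence names, and query-side coherence is deliberately not checked:
the reference coordinates alone define the region. Each final region
reports the number of input inverted blocks overlapping it and the
count of genes overlapping it by at least one base. The original
procedure was validated by manual inspection of dot plots; here that
step is replaced by planted-truth recovery tests on synthetic pairs.

## Gene correspondence

Method **M1** anchors on reciprocal best hits — best means highest bit
score, ties broken by lower e-value then lexicographically smaller
partner id — that lie on the same chromosome in both annotations.
Unanchored genes are then enriched by synteny: the gene's single best
*surviving* hit (identity > 80 % and alignment covering > 80 % of the
query or of the target — either denominator suffices, as printed) is
accepted when the partner lies, in partner-side coordinates, between
the partners of the nearest flanking anchors on the gene's chromosome.
Enrichment needs at least two anchors per chromosome; at chromosome
ends a single nearest anchor with a 5-Mb distance cap substitutes for
the missing bracket, since unbounded acceptance off one anchor would
otherwise be possible. Gene positions are span starts.

Method **M2** keeps a pair when hits exist in both directions, each
with ≥ 95 % identity and an alignment length of at least 50 % of the
query protein (the common convention for the denominator; configurable
to the minimum of both lengths), with both genes on the same
chromosome. Genes on unplaced scaffolds are admissible in M2 (flag,
default on) but never anchor M1. Multiple surviving partners resolve
by highest bit score.

`combine_methods` classifies each gene of the older annotation as
shared (same partner in both methods), method-specific, or discordant
(different partners); discordant genes are excluded from the final
table. The summary reports raw set algebra — counts for each class and
the final size — with the shared percentage computed against the M1
count. Genes whose chromosome cannot be resolved are quarantined into
a report rather than silently dropped, because both methods depend on
the same-chromosome test.

Protein hit tables are the standard 12-column tabular format; since
that format carries no protein lengths, a 14-column variant with query
and target lengths appended (the usual `qlen`/`slen` extension) is
accepted, and lengths may also be supplied as explicit mappings.

## Splicing events

Long-read alignments arrive as exon chains (BED12, optionally extended
with identity and read-coverage columns). Two retention presets exist:
the gene-prediction input filter (≥ 80 % of the read aligned at ≥ 95 %
identity) and a relaxed event-calling preset (> 90 % identity).
Redundancy reduction clusters chains by genomic-span overlap
(single linkage) and keeps the highest-scoring chain per cluster, ties
by longer span then read id.

A chain is assigned to the gene with maximal span overlap; chains
touching no gene are ignored. **Intron retention**: some read exon
entirely contains an annotated intron (inclusive containment).
**Exon skipping**: some read intron strictly shorter than 3 kb entirely
contains an annotated *internal* exon — terminal exons are never
callable, and the 3-kb guard suppresses mapping artefacts. The guard
applies to the read intron by default; a flag moves it to the exon,
since the prose definition admits either reading. Event identity is
(gene, feature interval); supporting reads accumulate, so duplicated
input is idempotent.

Short-read intron retention consumes a precomputed table of minimum
unspliced-read depth per annotated intron and calls an intron retained
when that minimum meets the threshold; by construction the 10 → 8 → 5
sweep is monotone, matching the observed direction that lower coverage
cutoffs call more retentions. Canonical splice-site fractions test
both orientations (GT..AG forward, CT..AC as its reverse complement)
on the genome sequence.

## Region context

**Gap placement.** A gap from another assembly is placed when some
(left, right) flank-alignment pair hits the same reference sequence,
each flank scores > 4,000 and aligns ≥ 1 kb, and the enclosing span —
leftmost flank start to rightmost flank end — is < 100 kb. The span
reading matches the reported mean placed-region size being span-like.
Among qualifying pairs the minimal span wins (the stated criteria give
no tie rule). Every input gap is either placed or rejected with a
recorded reason, so accounting is total.

**Repeat composition** resolves overlapping annotations by union —
globally for the masked fraction, per class for the class table — so
no base is double-counted within a class.

**Pericentromeres** run from the rightmost left-flank marker to the
leftmost right-flank marker on each chromosome, markers being point
positions (midpoints; the alternative hit-boundary reading differs by
a few bases at most). Inverted flanks flag the chromosome instead of
producing a call, which is itself a misassembly signal. A comparison
helper reports per-chromosome size and gene-count fold changes between
two assemblies.

**Methylation.** A CpG is methylated iff its frequency is strictly
above 0.5 and its depth is at least 4. The 100-kb window track reports
called / assessed sites per window, where assessed means covered by at
least one read; windows tile each sequence from 0, and a feature
counts in the window containing its start. Whether such density tracks
should count features or covered bases is left open by convention, so
both a count and a covered-base fraction are exposed per window.

## Assembly metrics

Contigs are maximal runs without N-runs of length ≥ `min_gap_run`
(default 1: any N splits, the plain reading of "splitting sequences at
each gap"); per-chromosome gap counts are the number of splitting
runs. N50 is the length at which the descending cumulative sum first
reaches half the total, L50 its 1-based rank. Lowercase soft-masked
bases count as ACGT — masking is annotation, not missing sequence.
Cumulative and anchored sizes are reported both with and without N.

## Synthetic data

The generators are pure functions of (parameters, seed) — identical
calls produce byte-identical files — and serialise their planted truth
beside the data. Default scales are desk-sized so the full suite runs
in seconds; the real counterparts are hundred-megabase assemblies,
~100,000-gene annotations and millions of reads. Planting is
deterministic (first-k assignment) so counts are exact.

* **Genome pair**: 3 chromosomes × 8 Mb, three 0.8–2 Mb inversions
  fragmented into 40–90 kb inverted sub-blocks with 10–80 kb gaps
  (below the first merge distance), first and last sub-block flush
  with the inversion ends; 25 decoy inverted blocks of 5–80 kb, half
  below the identity filter, all kept ≥ 110 kb clear of other inverted
  intervals so no decoy chain can reach a reportable size; planted
  inversions ≥ 1.5 Mb apart so the final merge cannot fuse them;
  forward blocks tile the rest. Identities are drawn at 98.2–99.9 %
  for true blocks (rounded to the dialect's two decimals).
* **Proteome pair**: 2,000 genes on 2 chromosomes, classes planted
  deterministically and spread evenly — clean reciprocal orthologs,
  anchors below the M2 identity floor (M1-only), one-directional hits
  recoverable only by synteny enrichment, cross-chromosome distractor
  winners whose true partner passes only M2, ambiguous paralogs that
  make the methods disagree (discordant), and 10 % decoy genes with
  one-directional sub-80 %-identity hits that must never be accepted.
* **Transcripts**: 500 five-exon genes on one chromosome; reads are
  noise-free exon chains from the planted isoforms; the first 10 % of
  genes carry a retained middle intron, the next 5 % a skipped middle
  exon (read intron ≤ ~1.9 kb, inside the guard); canonical GT..AG is
  written into the genome for the first 95 % of introns, the rest get
  a GC donor that matches neither orientation. A per-intron
  minimum-depth table with depths 0–15 makes the short-read sweep
  informative.
* **Region fixtures**: 100 gaps (first half placeable by construction,
  the rest cycling through the rejection reasons), repeat annotations
  in five classes, three flanking markers per centromere side, and
  2,000 CpG sites whose truth is threshold-separated (methylated:
  frequency ≥ 0.55 at depth ≥ 4; unmethylated: frequency ≤ 0.45 or
  depth ≤ 3).

What the generators do **not** model: alignment noise and fragmented
chains, read sequencing errors (event recovery is therefore tested at
precision = recall = 1, which real noisy reads will not attain),
many-to-many paralogy beyond the planted decoys, repeat-driven
spurious alignments, and nanopore signal artefacts. Passing tests
demonstrate the correctness of the decision rules and bookkeeping at
the stated thresholds, not robustness to those noise sources.

## Numerical and degenerate-input choices

Reported percentages use half-up decimal rounding (the convention of
printed one-decimal figures). Merging with `max_gap = 0` merges
overlapping and bookended intervals. Empty block lists, empty event
sets and unplaced-only assemblies are valid inputs yielding empty
outputs; empty sequence sets and empty length lists are errors. Ties
are broken deterministically everywhere (documented per operation), so
identical inputs give byte-identical outputs. Readers reject malformed
rows with file and line number rather than skipping them.

## Known limitations

* The staged inversion ladder reports a merged region even when the
  final 1-Mb merge fuses two independently qualifying regions; regions
  are strictly per-sequence, so inversions spanning unanchored
  scaffold joins are invisible.
* Synteny enrichment considers only the single best surviving hit per
  gene; a gene whose best hit is a distractor is lost to M1 even if a
  lower-scoring hit would have bracketed correctly.
* The short-read retention rule (minimum depth over the intron) is one
  admissible operationalisation of coverage-based calling; upstream
  depth computation is out of scope.
* No 5′/3′ alternative splice-site calling: read ends are too noisy
  for it, which is also why event definitions use full containment.
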
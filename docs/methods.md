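# Methods

## Scope and data model

`lnckit` re-implements the annotation-integration and characterization
computations used to build consolidated lncRNA catalogues: stepwise merging
of gene annotations from multiple sources, tissue-specificity scoring,
expression filtering and normalization, exon-level conservation
aggregation, and rule-based positional classification of lncRNA
transcripts against a protein-coding reference.

Annotations are held as a gene → transcript → exon hierarchy
(`AnnotationSet`), indexed by chromosome. Coordinates are 0-based
half-open internally; GFF3/GTF input and output use the formats' 1-based
inclusive convention and conversion happens only at the I/O boundary.
Every transcript carries a source tag, so gene-level provenance (the
union of transcript sources) survives merging and round-trips through
files: the writer places the tag in the GFF source column and the parser
reads it back. Feature types other than gene/transcript/exon are ignored
on input; the pipeline operates only on those three levels. Strand `.`
is permitted and treated as unknown.

Files that carry transcripts or exons without a gene record are common
among lncRNA databases. Such orphans are resolved by gene synthesis: one
gene per orphan `gene_id`, spanning the first exon start to the last exon
end over all its transcripts, on the transcript strand (conflicting
chromosomes are an error; conflicting strands give strand `.` with a
warning). Redundancy removal collapses transcripts with identical
(chromosome, strand, ordered exon-coordinate chain) to the first-seen
record and drops genes emptied by the collapse; identity is the full exon
chain, not the span, so two transcripts with the same span but different
internal boundaries are distinct.

## Stepwise intersection merge

An ordered list of candidate annotations is folded into a reference one
source at a time. For each candidate gene exactly one of three overlap
classes holds against the reference gene boundaries:

* **enclosed or full** — some reference gene `R` on the same chromosome
  satisfies `R.start ≤ c.start` and `c.end ≤ R.end` (identical boundaries
  are a sub-case). The candidate's transcripts are admitted into `R`:
  transcripts whose span escapes `R`'s boundary are discarded
  (out-of-bounds), transcripts whose exon chain already exists are
  skipped as duplicates, all others are added with their exons and source
  tag. The reference boundary is never changed.
* **partial** — the candidate straddles a reference boundary (including
  the case where the candidate strictly encloses a reference gene). The
  whole gene and its transcripts are discarded: admitting it would
  re-define reference gene boundaries, which the merge never does.
* **none** — no reference gene shares a base. The gene is added wholesale
  as a new lncRNA entry.

Gene-level overlap is strand-agnostic by default (a flag enables
strand-aware matching): antisense lncRNA transcripts are deliberately
admitted into protein-coding gene records, which is where a large share
of lncRNA transcripts reside. When several reference genes enclose a
candidate, the one with the largest base overlap wins, then the smallest
reference span, then the smallest gene id — deterministic and documented
rather than arbitrary. Enclosure beats partial overlap with some other
gene, since the discard rule exists only to protect boundaries and
enclosure respects them.

Candidates within one step are classified against the reference as it
stood at the start of the step; genes added in step *k* become reference
for step *k + 1*. Merging is therefore order-sensitive by design, and the
`MergeReport` accounts for every input gene and transcript in exactly one
fate category, so fate counts always sum to input counts. Gene-id
collisions with the growing reference are resolved by suffixing the
source tag and recorded in the report. Upset-style accounting
(`contribution_matrix`) counts genes by the exact combination of their
transcripts' source tags.

## Tissue specificity

Counts are converted to TPM per sample (`rate_g = count_g /
(length_g/1000)`, scaled to sum to 10⁶), replicates are averaged per
tissue arithmetically, and two scores are computed on the genes × tissues
matrix:

* **Tau**: with `x̂_i = x_i / max_i x_i`, `τ = Σ_i (1 − x̂_i) / (N − 1)`;
  0 for uniform expression, 1 for single-tissue expression. By default
  tissue means are log2(x+1)-transformed first (standard practice for
  skewed expression data); a raw mode is available and is what the
  closed-form examples use.
* **PEM**: `PEM_gt = log10(observed_gt / expected_gt)` with
  `expected_gt = r_g·c_t/G` from row/column/grand totals — an
  independence model over genes and tissues. Cells with zero observed
  expression are reported missing rather than −∞ so per-gene maxima stay
  finite. The per-gene maximum is min–max rescaled to [0, 1] across genes
  within the run (`pem_max_norm`); the rescaling choice is ours, as no
  standard exists for it.

Genes with zero expression in every tissue are excluded before scoring
(the permissive reading of the exclusion rule; a strict mode requiring
expression in all tissues exists behind a flag — the permissive reading
is the default because the strict one would bar exactly the single-tissue
genes a specificity analysis is about).

Note two properties that are sometimes assumed but do not hold:
duplicating a tissue column does not preserve the across-gene ordering of
raw-mode Tau (it maps `τ` to `((N−1)τ + (1−x̂_d))/N`, which can cross), and
log2-CPM is depth-invariant only asymptotically, because of the prior
count (see below).

## Expression filters and TMM/log2-CPM

Samples with fewer than 10⁶ reads assigned to genes are dropped (strict:
exactly 10⁶ is kept). Genes are kept when TPM > 0.50 in at least
⌈0.20·n⌉ samples *and* raw counts exceed a biotype threshold (> 2
protein-coding, > 1 non-coding) in at least ⌈0.20·n⌉ samples; all
comparisons are strict and the 20% uses a ceiling, so with n = 10 exactly
two qualifying samples suffice. A co-expression-network preset
(log2-CPM > 2 in ≥ 50% of samples) is provided as an alternative
pre-filter; network construction itself is out of scope.

Between-sample normalization uses trimmed mean of M-values: the reference
sample is the one whose 75th CPM percentile is closest to the mean of
those percentiles; per sample, genes zero in either sample are excluded,
log ratios M and abundances A are doubly trimmed (30% on M, 5% on A, each
end, rank-based), and the factor is 2 to the precision-weighted mean of
the surviving M values (inverse asymptotic binomial variance weights),
rescaled to geometric mean 1. This implementation was written from the
published recipe; the test suite checks it against an independent
straight-line reimplementation, and during development it agreed with the
canonical R implementation to 8 decimal places on a shared fixture.
log2-CPM is `log2((count + 0.5) / (libsize·factor + 1) × 10⁶)`; the 0.5
prior and +1 offset follow the standard recipe. The prior makes log2-CPM
depth-dependent at low counts (≈ 4.5/(10·c·ln 2) per gene for a 10× depth
change), vanishing for deep libraries.

The pipeline order is filter samples → filter genes → TMM → log2-CPM,
matching the order the filters are stated in.

## Conservation

Overlapping exons are merged by interval union before scoring so no base
is counted twice. The default scope is per gene (all transcripts pooled),
because gene-level summaries are the stated product; a per-transcript
scope is exposed. Scores come from a per-base track of sorted
non-overlapping (start, end, score) runs; text BedGraph is the on-disk
format. The mean over an exon is taken over covered bases only by default
(`ignore`, the mean-over-covered convention of genome-browser averaging
tools), or counting uncovered bases as zero (`zero`); a fully uncovered
exon is missing under `ignore`. Exact arithmetic over run overlaps makes
the result identical (to ~1e-15) to a per-base expansion.

## Positional classification

Candidates shorter than 200 bp of summed exon length are removed (size is
transcript sequence length, not genomic span — the filter targets the
RNA, and monoexonic transcripts are explicitly retained); candidates
whose same-strand exonic overlap with reference protein-coding exons
exceeds 0.75 of their own exonic length are removed as likely unannotated
coding isoforms (the rule applies in sense only; antisense overlap never
removes).

A (lncRNA, partner) pair sharing ≥ 1 base is **genic**: sense/antisense
by strand equality; exonic/intronic by exon–exon overlap; nested /
containing / overlapping by span relation, with nested tested first so
identical spans classify as nested. A disjoint pair within the search
window is **intergenic**: the distance is the gap between nearest span
boundaries; upstream/downstream is the partner's position relative to the
lncRNA's 5′ end; orientation is same_strand for equal strands, else
divergent when the 5′ ends face each other (head-to-head) and convergent
when the 3′ ends face (tail-to-tail). This geometry forces
opposite-strand upstream pairs to be divergent and downstream pairs
convergent, so the upstream-convergent and downstream-divergent cells of
the count grid are structurally empty. Flipping both strands maps
(upstream, divergent) ↔ (downstream, convergent) and preserves
same_strand and sense/antisense — orientation labels themselves are not
invariant under a global strand flip.

All genic interactions are reported, plus all intergenic interactions
with gap ≤ 100 kb (default window). A strict-band mode restricts
intergenic partners to gap ≥ 10 kb; the default reports everything within
the maximum window, which subsumes any expanding-radius search. One best
partner is flagged per classified lncRNA: genic beats intergenic; among
genic, largest exonic overlap, then largest span overlap, then smallest
id; among intergenic, smallest distance, then smallest id. lncRNAs with
no partner in the window are counted as unclassified.

## Synthetic fixtures

All fixtures are pure functions of a seed on short synthetic contigs
(≤ 10⁶ bp, so brute-force per-base oracles are feasible) and record
ground truth for every planted record.

* `gen_annotations` engineers candidate genes enclosed / partial /
  disjoint versus a reference in requested proportions (default
  0.4/0.2/0.4), with planted duplicate and boundary-escaping transcripts;
  intended merge fates are recorded.
* `labelled_merge_scenario` hand-builds the canonical two-annotation
  configuration (enclosed gene with one escaping and two admissible
  transcripts; straddling gene; disjoint gene).
* `gen_expression` draws negative-binomial counts (dispersion size 10,
  ±15% library wobble) over 31 tissues × 3 replicates by default — 31
  matches the solid-tissue panel the scores are designed for, while 3
  replicates keep fixtures small; real cohorts have hundreds of samples
  per tissue, and nothing in the scores depends on replicate count beyond
  averaging. Planted specific genes are near-silent (mean 1) outside one
  tissue and boosted ~200–400× within it; ubiquitous genes share a
  log-normal mean across tissues. This emulates tissue structure only: no
  batch effects, GC/length bias, isoform switching or correlated genes,
  so passing tests demonstrate correctness of the computations, not
  robustness to those artefacts.
* `gen_score_track` writes piecewise-constant runs (default 80% coverage,
  scores U[0, 0.3]) with optional high-score runs (U[0.8, 1.0]) overlaid
  on designated exons.
* `gen_classification` plants isolated (lncRNA, mRNA) pairs realizing
  each of the 12 genic and 4 feasible intergenic classes, separated by
  250 kb so the planted class is the only record.

## Numerical and degenerate-input choices

* All-zero expression columns stay all-zero with a warning under TPM;
  all-zero genes are excluded from scoring and reported.
* TMM errors on all-zero samples (no factor is defined); factors get a
  1.0 fallback when trimming leaves nothing.
* Ties in trimming ranks use average ranks; M/A values are continuous so
  ties are measure-zero in practice.
* `merge_exons` on a transcriptless gene is an error; empty annotation
  sets write header-only files and parse back to empty sets.
* Fixture problem sizes in the test-suite and the reproduction script
  (tens of genes per annotation fixture, 100-fixture oracle batches,
  1000-gene expression panels) were chosen so the whole suite runs in
  seconds while every code path and boundary case is exercised; the
  algorithms are linear or n·log n in records and run unchanged on
  full-genome inputs.

## Known limitations

* The merge never re-defines reference boundaries; a candidate gene
  strictly containing a reference gene is discarded even if its extra
  exons are well supported.
* Within one merge step candidates do not see each other, so two
  mutually overlapping NONE genes are both added; deduplication handles
  identical chains but not near-duplicates.
* PEM's independence model is sensitive to the tissue panel composition;
  adding correlated tissues shifts expected values.
* The coding-potential machine-learning score of the upstream tool this
  classifier mirrors is out of scope; the classifier is purely
  positional.
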
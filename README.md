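# lnckit

Toolkit for building and characterizing consolidated long non-coding RNA
(lncRNA) catalogues from multiple gene annotations.

lncRNA databases disagree: the same locus may appear in several sources
with different boundaries, transcript models and identifiers, and no
single database is complete. `lnckit` implements the computations needed
to integrate such sources into one non-redundant catalogue and to
characterize the result:

* **Stepwise intersection merge** — fold an ordered list of candidate
  GFF3/GTF annotations into a reference. A candidate gene enclosed within
  a reference gene boundary contributes its novel transcripts to that
  gene; a gene straddling a boundary is discarded (reference boundaries
  are never re-defined); a gene overlapping nothing is added as a new
  lncRNA entry. Every input record's fate is accounted for, with
  upset-style source-membership counts of the merged result.
* **Tissue specificity** — TPM normalization, per-tissue replicate
  averaging, and two scores per gene: Tau,
  `τ = Σᵢ(1 − x̂ᵢ)/(N − 1)` with `x̂ᵢ = xᵢ/maxᵢxᵢ` over N tissues
  (0 = ubiquitous, 1 = single-tissue), and the preferential expression
  measure `PEM_gt = log₁₀(observed_gt/expected_gt)` under an independence
  model `expected_gt = r_g·c_t/G`.
* **Expression preparation** — the sample filter (≥ 10⁶ assigned reads),
  the two-step gene filter (TPM > 0.5 and counts > 2 / > 1 for coding /
  non-coding genes, each in ≥ 20% of samples), trimmed-mean-of-M-values
  (TMM) scaling factors and `log₂((count + 0.5)/(lib·factor + 1)·10⁶)`.
* **Conservation** — union-merge of overlapping exons and per-exon mean
  conservation scores from a per-base BedGraph track, with per-biotype
  summaries.
* **Positional classification** — each lncRNA transcript versus reference
  mRNA partners: genic (sense/antisense × exonic/intronic ×
  nested/containing/overlapping) or intergenic within a 100 kb window
  (upstream/downstream × divergent/convergent/same_strand), after the
  200 bp size and 0.75 sense-overlap pre-filters.

Everything is testable offline: `lnckit.fixtures` generates annotations,
expression matrices and score tracks on synthetic contigs with recorded
ground truth. See `docs/methods.md` for the full method description and
the design decisions.

## Worked example

```python
import pandas as pd
import lnckit as lk
from lnckit import fixtures as fx

# a hand-built two-annotation scenario: one enclosed gene (with one
# boundary-escaping transcript), one straddling gene, one disjoint gene
ref, cand = fx.labelled_merge_scenario()
merged, report = lk.merge_pair(ref, cand)
print(report.summary())
```

```
{'genes_merged_into': 1, 'genes_added_new': 1, 'genes_discarded_partial': 1,
 'transcripts_added': 4, 'transcripts_duplicate_skipped': 0,
 'transcripts_discarded_out_of_bounds': 1,
 'transcripts_discarded_with_partial_gene': 1}
```

The enclosed gene merged into its reference gene (its two in-bounds
transcripts admitted, the escaping one discarded), the straddling gene
was discarded whole, and the disjoint gene was added with both
transcripts: 4 of 6 candidate transcripts entered the catalogue.

```python
table, counts = lk.contribution_matrix(merged)
print(counts)
```

```
combination
cand&ref    1
ref         1
cand        1
Name: n_genes, dtype: int64
```

One gene now carries transcripts from both sources, one is
reference-only, one came wholly from the candidate.

```python
e = pd.DataFrame([[8, 0, 0, 0], [5, 5, 5, 5], [8, 2, 2, 2]],
                 index=["specific", "ubiquitous", "graded"],
                 columns=["heart", "liver", "lung", "brain"], dtype=float)
tau, _ = lk.tau(e, log_transform=False)
print(tau)
```

```
specific      1.00
ubiquitous    0.00
graded        0.75
```

A gene expressed in a single tissue scores τ = 1, a uniformly expressed
gene 0, and the (8,2,2,2) profile 0.75.

The same operations are available from the shell:

```bash
lnckit fixtures --preset merge --seed 1 -o fixtures/
lnckit merge --reference fixtures/reference.gff3 \
    --candidates fixtures/src1.gff3 --candidates fixtures/src2.gff3 \
    --report report.tsv --upset upset.tsv -o merged.gff3
lnckit classify --lnc cand.gff3 --ref ref.gff3 -o classes.tsv
```

Each run writes a `*.manifest.json` with inputs, parameters and output
checksums; fixed inputs reproduce byte-identical outputs.

## Full-scale use

The synthetic fixtures stand in for the six public annotation releases
(CHESS, FANTOM, LNCipedia, NONCODE, MiTranscriptome, BIGTranscriptome)
and the GTEx expression panel that a production catalogue build would
use. To run at full scale, download those GFFs, lift everything to one
genome build, then `lnckit merge` with the reference first and candidates
in decreasing order of experimental support; feed gene-level counts and
TPM from your quantifier into `lnckit prep` / `lnckit specificity`, and a
genome-browser conservation track (converted to BedGraph) into
`lnckit conserve`. Headline catalogue sizes depend on the exact source
versions used.
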
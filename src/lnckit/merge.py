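"""Cumulative stepwise intersection of gene annotations.

An ordered list of candidate annotations is folded into a reference
annotation one source at a time. For each candidate gene the decision is
purely positional:

* enclosed within (or coinciding with) a reference gene boundary — its
  transcripts are admitted into that reference gene, provided each
  transcript span stays inside the gene boundary and its exon chain is not
  already present;
* partially overlapping a reference gene boundary — the whole gene and its
  transcripts are discarded, because admitting it would re-define reference
  gene boundaries;
* sharing no base with any reference gene — the gene is added wholesale as
  a new lncRNA entry.

Reference gene boundaries are never altered. Every input gene and
transcript is accounted for in exactly one fate category of the
:class:`MergeReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .model import AnnotationSet, Gene, Transcript


class OverlapClass(Enum):
    ENCLOSED_OR_FULL = "enclosed_or_full"
    PARTIAL = "partial"
    NONE = "none"


# gene fates
MERGED_INTO = "merged_into"
ADDED_NEW = "added_new"
DISCARDED_PARTIAL = "discarded_partial"
# transcript fates
ADDED = "added"
DUPLICATE_SKIPPED = "duplicate_skipped"
DISCARDED_OUT_OF_BOUNDS = "discarded_out_of_bounds"
DISCARDED_WITH_PARTIAL_GENE = "discarded_with_partial_gene"

_GENE_FATES = (MERGED_INTO, ADDED_NEW, DISCARDED_PARTIAL)
_TX_FATES = (
    ADDED, DUPLICATE_SKIPPED, DISCARDED_OUT_OF_BOUNDS, DISCARDED_WITH_PARTIAL_GENE,
)


@dataclass
class MergeReport:
    """Per-record fate accounting for one merge step."""

    step: str
    #: gene_id -> (fate, target reference gene id or None)
    gene_fates: Dict[str, Tuple[str, Optional[str]]] = field(default_factory=dict)
    #: transcript_id -> fate
    transcript_fates: Dict[str, str] = field(default_factory=dict)
    #: candidate gene ids renamed on collision: old -> new
    renamed: Dict[str, str] = field(default_factory=dict)

    def gene_counts(self) -> Dict[str, int]:
        counts = {f: 0 for f in _GENE_FATES}
        for fate, _ in self.gene_fates.values():
            counts[fate] += 1
        return counts

    def transcript_counts(self) -> Dict[str, int]:
        counts = {f: 0 for f in _TX_FATES}
        for fate in self.transcript_fates.values():
            counts[fate] += 1
        return counts

    def summary(self) -> Dict[str, int]:
        out = {f"genes_{k}": v for k, v in self.gene_counts().items()}
        out.update({f"transcripts_{k}": v for k, v in self.transcript_counts().items()})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step": self.step, "record_type": "gene", "record_id": gid,
                "fate": fate, "target": target or "",
            }
            for gid, (fate, target) in sorted(self.gene_fates.items())
        ]
        rows += [
            {
                "step": self.step, "record_type": "transcript", "record_id": tid,
                "fate": fate, "target": "",
            }
            for tid, fate in sorted(self.transcript_fates.items())
        ]
        return pd.DataFrame(
            rows, columns=["step", "record_type", "record_id", "fate", "target"]
        )


def _strand_ok(ref_strand: str, cand_strand: str, strand_aware: bool) -> bool:
    if not strand_aware:
        return True
    return ref_strand == cand_strand


def _build_tree(reference: AnnotationSet) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom in reference.chroms():
        t = IntervalTree()
        for g in reference.genes_on(chrom):
            t.addi(g.start, g.end, g.id)
        trees[chrom] = t
    return trees


def classify_gene_overlap(
    candidate: Gene,
    reference: AnnotationSet,
    strand_aware: bool = False,
    _trees: Optional[Dict[str, IntervalTree]] = None,
) -> Tuple[OverlapClass, Optional[str]]:
    """Classify a candidate gene against the reference gene boundaries.

    Returns ``ENCLOSED_OR_FULL`` with the best enclosing reference gene id
    when some reference gene on the same chromosome (and strand, if
    ``strand_aware``) satisfies ``R.start <= c.start and c.end <= R.end``;
    ``NONE`` when no reference gene shares a base; ``PARTIAL`` otherwise.

    Among several enclosing genes the best is the one with the largest
    base overlap (for enclosure that is the candidate length, so ties are
    common), then the smallest reference span, then the smallest gene id.
    """
    trees = _trees if _trees is not None else _build_tree(reference)
    tree = trees.get(candidate.chrom)
    hits = []
    if tree is not None:
        for iv in tree.overlap(candidate.start, candidate.end):
            ref_gene = reference[iv.data]
            if _strand_ok(ref_gene.strand, candidate.strand, strand_aware):
                hits.append(ref_gene)
    if not hits:
        return OverlapClass.NONE, None
    enclosing = [
        r for r in hits if r.start <= candidate.start and candidate.end <= r.end
    ]
    if not enclosing:
        return OverlapClass.PARTIAL, None
    best = min(enclosing, key=lambda r: (-(candidate.end - candidate.start), len(r), r.id))
    return OverlapClass.ENCLOSED_OR_FULL, best.id


def admit_transcripts(
    reference_gene: Gene,
    candidate_transcripts: Sequence[Transcript],
) -> Tuple[Gene, Dict[str, str]]:
    """Admit candidate transcripts into an enclosing reference gene.

    A transcript whose span falls outside the gene boundary is discarded
    (``discarded_out_of_bounds``); one whose exon chain equals an existing
    transcript's chain is skipped as a duplicate; all others are added with
    their exons and source tag. The gene boundary is never changed.
    """
    fates: Dict[str, str] = {}
    chains = {t.chain_key() for t in reference_gene.transcripts}
    for t in candidate_transcripts:
        if t.chrom != reference_gene.chrom:
            raise ValueError(
                f"transcript {t.id} on {t.chrom} cannot join gene "
                f"{reference_gene.id} on {reference_gene.chrom}"
            )
        if t.start < reference_gene.start or t.end > reference_gene.end:
            fates[t.id] = DISCARDED_OUT_OF_BOUNDS
            continue
        key = t.chain_key()
        if key in chains:
            fates[t.id] = DUPLICATE_SKIPPED
            continue
        admitted = Transcript(t.id, reference_gene.id, t.source, biotype=t.biotype)
        admitted.exons = [e for e in t.exons]
        for e in admitted.exons:
            e.transcript_id = admitted.id
        reference_gene.transcripts.append(admitted)
        chains.add(key)
        fates[t.id] = ADDED
    return reference_gene, fates


def merge_pair(
    reference: AnnotationSet,
    candidate: AnnotationSet,
    strand_aware: bool = False,
) -> Tuple[AnnotationSet, MergeReport]:
    """One step of the stepwise intersection: fold ``candidate`` into ``reference``.

    Candidate genes are classified against the reference as it stands at
    the start of the step; genes added during the step become reference
    only for subsequent steps of :func:`merge_all`. The input reference is
    not mutated.
    """
    merged = reference.copy()
    report = MergeReport(step=candidate.name)
    trees = _build_tree(reference)

    for g in sorted(candidate.genes(), key=lambda g: (g.chrom, g.start, g.end, g.id)):
        cls, best = classify_gene_overlap(g, reference, strand_aware, _trees=trees)
        if cls is OverlapClass.PARTIAL:
            report.gene_fates[g.id] = (DISCARDED_PARTIAL, None)
            for t in g.transcripts:
                report.transcript_fates[t.id] = DISCARDED_WITH_PARTIAL_GENE
        elif cls is OverlapClass.ENCLOSED_OR_FULL:
            assert best is not None
            target = merged[best]
            _, fates = admit_transcripts(target, g.transcripts)
            report.gene_fates[g.id] = (MERGED_INTO, best)
            report.transcript_fates.update(fates)
        else:  # NONE -> new lncRNA entry
            new_id = g.id
            if new_id in merged:
                new_id = f"{g.id}_{candidate.name}"
                report.renamed[g.id] = new_id
            new_gene = Gene(
                new_id, g.chrom, g.strand, g.start, g.end, biotype="lncRNA"
            )
            for t in g.transcripts:
                nt = Transcript(t.id, new_id, t.source, biotype=t.biotype)
                nt.exons = [e for e in t.exons]
                new_gene.transcripts.append(nt)
                report.transcript_fates[t.id] = ADDED
            merged.add_gene(new_gene)
            report.gene_fates[g.id] = (ADDED_NEW, None)
    return merged, report


def merge_all(
    reference: AnnotationSet,
    candidates: Sequence[AnnotationSet],
    strand_aware: bool = False,
) -> Tuple[AnnotationSet, List[MergeReport]]:
    """Left fold of :func:`merge_pair` over an ordered candidate list."""
    merged = reference
    reports: List[MergeReport] = []
    for cand in candidates:
        merged, rep = merge_pair(merged, cand, strand_aware=strand_aware)
        reports.append(rep)
    if not candidates:
        merged = reference.copy()
    return merged, reports


def contribution_matrix(
    merged: AnnotationSet,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Upset-style source-membership accounting at the gene level.

    A gene's membership is the union of its transcripts' source tags.
    Returns a per-gene boolean membership table and the counts per exact
    non-empty source combination (index: sources joined with ``&``).
    """
    all_sources = sorted({s for g in merged.genes() for s in g.sources})
    rows = []
    combos: Dict[str, int] = {}
    for g in merged.genes():
        membership = {s: (s in g.sources) for s in all_sources}
        rows.append({"gene_id": g.id, **membership})
        key = "&".join(sorted(g.sources))
        combos[key] = combos.get(key, 0) + 1
    table = pd.DataFrame(rows, columns=["gene_id", *all_sources])
    counts = pd.Series(combos, dtype=int).sort_values(ascending=False)
    counts.index.name = "combination"
    counts.name = "n_genes"
    return table, counts
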
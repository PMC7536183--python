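"""Hierarchical annotation model: genes, transcripts and exons.

Coordinates are 0-based half-open internally; GFF3/GTF readers and writers
convert to and from the formats' 1-based inclusive convention at the
boundary (see :mod:`lnckit.gff_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set, Tuple

VALID_STRANDS = {"+", "-", "."}

Biotype = str  # one of "protein_coding", "lncRNA", "other"


@dataclass
class Exon:
    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"exon {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Transcript:
    id: str
    gene_id: str
    source: str
    exons: List[Exon] = field(default_factory=list)
    biotype: Biotype = "other"

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def exonic_length(self) -> int:
        """Summed exon length in bp (transcript sequence length)."""
        return sum(len(e) for e in self.exons)

    def exon_chain(self) -> Tuple[Tuple[int, int], ...]:
        """Ordered exon coordinate chain; the identity used for dedup."""
        return tuple(sorted(e.interval for e in self.exons))

    def chain_key(self) -> Tuple[str, str, Tuple[Tuple[int, int], ...]]:
        return (self.chrom, self.strand, self.exon_chain())

    def normalize(self) -> None:
        """Sort exons by start and validate shared chrom/strand."""
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"transcript {self.id} spans chromosomes {chroms}")
        strands = {e.strand for e in self.exons}
        if len(strands) > 1:
            raise ValueError(f"transcript {self.id} mixes strands {strands}")
        self.exons.sort(key=lambda e: (e.start, e.end))


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: Biotype = "other"
    transcripts: List[Transcript] = field(default_factory=list)

    @property
    def sources(self) -> Set[str]:
        return {t.source for t in self.transcripts}

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


class AnnotationSet:
    """A source-tagged collection of genes indexed by chromosome."""

    def __init__(self, name: str):
        self.name = name
        self._genes: Dict[str, Gene] = {}
        self._by_chrom: Dict[str, List[str]] = {}
        #: transcripts whose gene_id has no gene record yet; resolved by
        #: gff_io.synthesize_missing_genes
        self.orphan_transcripts: List[Transcript] = []

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    def genes(self) -> Iterator[Gene]:
        """Genes in (chrom, start, id) order."""
        for g in sorted(
            self._genes.values(), key=lambda g: (g.chrom, g.start, g.end, g.id)
        ):
            yield g

    def genes_on(self, chrom: str) -> List[Gene]:
        return [self._genes[gid] for gid in self._by_chrom.get(chrom, [])]

    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes():
            yield from g.transcripts

    def add_gene(self, gene: Gene) -> None:
        if gene.id in self._genes:
            raise ValueError(f"duplicate gene id {gene.id!r} in set {self.name!r}")
        self._genes[gene.id] = gene
        self._by_chrom.setdefault(gene.chrom, []).append(gene.id)

    def remove_gene(self, gene_id: str) -> Gene:
        gene = self._genes.pop(gene_id)
        self._by_chrom[gene.chrom].remove(gene_id)
        if not self._by_chrom[gene.chrom]:
            del self._by_chrom[gene.chrom]
        return gene

    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self._genes.values())

    def n_exons(self) -> int:
        return sum(len(t.exons) for g in self._genes.values() for t in g.transcripts)

    def copy(self, name: Optional[str] = None) -> "AnnotationSet":
        """Deep structural copy."""
        out = AnnotationSet(name if name is not None else self.name)
        for g in self.genes():
            ng = Gene(g.id, g.chrom, g.strand, g.start, g.end, g.biotype)
            for t in g.transcripts:
                nt = Transcript(t.id, t.gene_id, t.source, biotype=t.biotype)
                nt.exons = [
                    Exon(e.chrom, e.start, e.end, e.strand, e.transcript_id)
                    for e in t.exons
                ]
                ng.transcripts.append(nt)
            out.add_gene(ng)
        for t in self.orphan_transcripts:
            nt = Transcript(t.id, t.gene_id, t.source, biotype=t.biotype)
            nt.exons = [
                Exon(e.chrom, e.start, e.end, e.strand, e.transcript_id)
                for e in t.exons
            ]
            out.orphan_transcripts.append(nt)
        return out

    def structurally_equal(self, other: "AnnotationSet") -> bool:
        """Field-by-field equality of the gene→transcript→exon hierarchy."""
        mine = list(self.genes())
        theirs = list(other.genes())
        if len(mine) != len(theirs):
            return False
        for a, b in zip(mine, theirs):
            if (a.id, a.chrom, a.strand, a.start, a.end, a.biotype) != (
                b.id, b.chrom, b.strand, b.start, b.end, b.biotype,
            ):
                return False
            if len(a.transcripts) != len(b.transcripts):
                return False
            for ta, tb in zip(
                sorted(a.transcripts, key=lambda t: t.id),
                sorted(b.transcripts, key=lambda t: t.id),
            ):
                if (ta.id, ta.gene_id, ta.source, ta.biotype) != (
                    tb.id, tb.gene_id, tb.source, tb.biotype,
                ):
                    return False
                if [e.interval for e in ta.exons] != [e.interval for e in tb.exons]:
                    return False
                if {e.strand for e in ta.exons} != {e.strand for e in tb.exons}:
                    return False
        return True
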
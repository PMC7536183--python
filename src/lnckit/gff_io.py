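"""Reading, normalizing and writing GFF3/GTF gene annotations.

The parser accepts both dialects (auto-detected per file from the attribute
syntax), resolves gene→transcript→exon linkage through ``ID``/``Parent`` or
``gene_id``/``transcript_id`` attributes, and converts the formats' 1-based
inclusive coordinates to the package-internal 0-based half-open convention.

Feature types other than gene/transcript/exon (CDS, UTRs, ...) are ignored:
the merge pipeline operates on gene, transcript and exon blocks only.
Transcripts whose ``gene_id`` has no gene record are kept aside as orphans;
:func:`synthesize_missing_genes` builds gene records for them from the
first/last exon positions and the transcript strand.
"""

from __future__ import annotations

import warnings
from collections import Counter
from pathlib import Path
from typing import List, Optional, Tuple, Union

import pandas as pd
from gffutils.feature import feature_from_line

from .model import AnnotationSet, Exon, Gene, Transcript

_GENE_TYPES = {"gene"}
_TRANSCRIPT_TYPES = {"transcript", "mRNA", "lnc_RNA", "lincRNA"}
_EXON_TYPES = {"exon"}

_LNC_ALIASES = {"lncrna", "lincrna", "lnc_rna", "noncoding", "non_coding"}


class GffParseError(ValueError):
    """Raised for malformed annotation lines; message names the line number."""


def _norm_biotype(raw: Optional[str]) -> str:
    if raw is None:
        return "other"
    low = raw.lower()
    if low == "protein_coding":
        return "protein_coding"
    if low in _LNC_ALIASES:
        return "lncRNA"
    return "other"


def _attr(feature, *names: str) -> Optional[str]:
    for n in names:
        if n in feature.attributes:
            vals = feature.attributes[n]
            if vals:
                return vals[0]
    return None


def detect_dialect(path: Union[str, Path]) -> str:
    """Sniff ``gff3`` vs ``gtf`` from the attribute syntax of the first data line."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = fields[8]
            if "=" in attrs and '"' not in attrs.split("=", 1)[0]:
                return "gff3"
            return "gtf"
    return "gff3"


def parse_annotation(
    path: Union[str, Path],
    dialect: str = "auto",
    source_tag: Optional[str] = None,
) -> AnnotationSet:
    """Parse a GFF3/GTF file into a hierarchical :class:`AnnotationSet`.

    Parameters
    ----------
    path
        Annotation file, 1-based inclusive coordinates.
    dialect
        ``gff3``, ``gtf`` or ``auto`` (sniffed from the attribute syntax).
    source_tag
        Tag recorded on every transcript. When ``None`` the tag is taken
        from each record's source column, so provenance written by
        :func:`write_gff` round-trips.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = detect_dialect(path)
    if dialect not in {"gff3", "gtf"}:
        raise ValueError(f"unknown dialect {dialect!r}")

    name = source_tag if source_tag is not None else path.stem
    out = AnnotationSet(name)
    transcripts: dict = {}  # id -> Transcript
    gene_lines: List[Gene] = []
    pending_exons: List[Tuple[int, Exon]] = []  # (line no, exon) awaiting parents

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line, dialect=None, strict=False)
            except Exception as exc:
                raise GffParseError(f"{path}: line {lineno}: {exc}") from exc
            if f.start is None or f.end is None or not f.seqid:
                raise GffParseError(
                    f"{path}: line {lineno}: record lacks coordinates"
                )
            start0, end0 = int(f.start) - 1, int(f.end)  # to 0-based half-open
            if start0 >= end0:
                raise GffParseError(
                    f"{path}: line {lineno}: empty or inverted interval"
                )
            strand = f.strand if f.strand in {"+", "-"} else "."
            rec_source = source_tag if source_tag is not None else (f.source or name)
            ftype = f.featuretype

            if ftype in _GENE_TYPES:
                gid = _attr(f, "ID", "gene_id")
                if gid is None:
                    raise GffParseError(
                        f"{path}: line {lineno}: gene record without ID/gene_id"
                    )
                bio = _norm_biotype(
                    _attr(f, "biotype", "gene_biotype", "gene_type")
                )
                gene_lines.append(Gene(gid, f.seqid, strand, start0, end0, bio))
            elif ftype in _TRANSCRIPT_TYPES:
                tid = _attr(f, "ID", "transcript_id")
                gid = _attr(f, "Parent", "gene_id")
                if tid is None:
                    raise GffParseError(
                        f"{path}: line {lineno}: transcript without "
                        "ID/transcript_id"
                    )
                if gid is None:
                    gid = tid  # degenerate file: transcript is its own gene
                bio = _norm_biotype(
                    _attr(f, "biotype", "transcript_biotype", "transcript_type")
                )
                transcripts[tid] = Transcript(tid, gid, rec_source, biotype=bio)
            elif ftype in _EXON_TYPES:
                tid = _attr(f, "Parent", "transcript_id")
                if tid is None:
                    raise GffParseError(
                        f"{path}: line {lineno}: exon with no resolvable "
                        "transcript parent and no transcript_id"
                    )
                exon = Exon(f.seqid, start0, end0, strand, tid)
                if tid in transcripts:
                    transcripts[tid].exons.append(exon)
                else:
                    pending_exons.append((lineno, exon))
            # other feature types are ignored

    for lineno, exon in pending_exons:
        tid = exon.transcript_id
        if tid not in transcripts:
            # exon carries a transcript_id but no transcript record exists:
            # synthesize a bare transcript (its gene comes later)
            gid = tid
            transcripts[tid] = Transcript(tid, gid, name)
        transcripts[tid].exons.append(exon)

    for t in transcripts.values():
        if not t.exons:
            warnings.warn(f"transcript {t.id} has no exon records; dropped")
    transcripts = {tid: t for tid, t in transcripts.items() if t.exons}
    for t in transcripts.values():
        t.normalize()

    by_gene: dict = {}
    for t in transcripts.values():
        by_gene.setdefault(t.gene_id, []).append(t)

    for g in gene_lines:
        g.transcripts = sorted(by_gene.pop(g.id, []), key=lambda t: t.id)
        out.add_gene(g)
    # transcripts whose gene_id has no gene record stay orphans until
    # synthesize_missing_genes
    for gid in sorted(by_gene):
        out.orphan_transcripts.extend(sorted(by_gene[gid], key=lambda t: t.id))
    return out


def synthesize_missing_genes(aset: AnnotationSet) -> AnnotationSet:
    """Create gene records for orphan transcripts.

    For each orphan ``gene_id`` one gene is built spanning from the first
    exon start to the last exon end over all of its transcripts, on the
    transcript strand. Conflicting chromosomes within one gene_id are an
    error; conflicting strands yield strand ``.`` with a warning. Existing
    genes are untouched.
    """
    by_gene: dict = {}
    for t in aset.orphan_transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid in sorted(by_gene):
        ts = by_gene[gid]
        chroms = {t.chrom for t in ts}
        if len(chroms) > 1:
            raise ValueError(
                f"orphan transcripts of gene {gid!r} span chromosomes {sorted(chroms)}"
            )
        strands = {t.strand for t in ts}
        if len(strands) > 1:
            warnings.warn(
                f"orphan transcripts of gene {gid!r} disagree on strand; using '.'"
            )
            strand = "."
        else:
            strand = next(iter(strands))
        start = min(t.start for t in ts)
        end = max(t.end for t in ts)
        bios = Counter(t.biotype for t in ts)
        gene = Gene(
            gid, next(iter(chroms)), strand, start, end,
            biotype=bios.most_common(1)[0][0],
            transcripts=sorted(ts, key=lambda t: t.id),
        )
        if gid in aset:
            raise ValueError(f"orphan gene_id {gid!r} collides with an existing gene")
        aset.add_gene(gene)
    aset.orphan_transcripts = []
    return aset


def deduplicate(aset: AnnotationSet) -> Tuple[AnnotationSet, int]:
    """Remove redundant records within a set.

    Transcripts with the same exonic start and end coordinates — identical
    (chrom, strand, ordered exon chain) — collapse to the first-seen one
    (iteration order: gene (chrom, start, id), then transcript id). Genes
    emptied by the collapse are removed. Returns the set and the number of
    removed records (transcripts plus emptied genes).
    """
    seen: set = set()
    removed = 0
    empty_genes: List[str] = []
    for g in aset.genes():
        kept: List[Transcript] = []
        for t in g.transcripts:
            key = t.chain_key()
            if key in seen:
                removed += 1
            else:
                seen.add(key)
                kept.append(t)
        g.transcripts = kept
        if not kept:
            empty_genes.append(g.id)
    for gid in empty_genes:
        aset.remove_gene(gid)
        removed += 1
    return aset, removed


def _fmt_attrs(dialect: str, pairs: List[Tuple[str, str]]) -> str:
    if dialect == "gff3":
        return ";".join(f"{k}={v}" for k, v in pairs)
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gff(
    aset: AnnotationSet, path: Union[str, Path], dialect: str = "gff3"
) -> None:
    """Write a set as GFF3 or GTF, 1-based inclusive.

    Genes are sorted by (chrom, start); transcripts nest under genes and
    exons under transcripts. The source column carries each transcript's
    source tag so that provenance survives a round-trip.
    """
    if dialect not in {"gff3", "gtf"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    if aset.orphan_transcripts:
        raise ValueError(
            "set has orphan transcripts; run synthesize_missing_genes first"
        )
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        else:
            fh.write(f"#!annotation-set {aset.name}\n")
        for g in aset.genes():
            srcs = ",".join(sorted(g.sources)) or aset.name
            if dialect == "gff3":
                attrs = _fmt_attrs(dialect, [
                    ("ID", g.id), ("biotype", g.biotype), ("sources", srcs),
                ])
            else:
                attrs = _fmt_attrs(dialect, [
                    ("gene_id", g.id), ("biotype", g.biotype), ("sources", srcs),
                ])
            fh.write(
                f"{g.chrom}\t{srcs}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t in sorted(g.transcripts, key=lambda t: (t.start, t.end, t.id)):
                if dialect == "gff3":
                    attrs = _fmt_attrs(dialect, [
                        ("ID", t.id), ("Parent", g.id), ("biotype", t.biotype),
                    ])
                else:
                    attrs = _fmt_attrs(dialect, [
                        ("gene_id", g.id), ("transcript_id", t.id),
                        ("biotype", t.biotype),
                    ])
                fh.write(
                    f"{t.chrom}\t{t.source}\ttranscript\t{t.start + 1}\t{t.end}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    if dialect == "gff3":
                        attrs = _fmt_attrs(dialect, [("Parent", t.id)])
                    else:
                        attrs = _fmt_attrs(dialect, [
                            ("gene_id", g.id), ("transcript_id", t.id),
                        ])
                    fh.write(
                        f"{e.chrom}\t{t.source}\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{e.strand}\t.\t{attrs}\n"
                    )


def annotation_table(aset: AnnotationSet) -> pd.DataFrame:
    """Flat per-transcript table (the downloadable text/CSV dump)."""
    rows = []
    for g in aset.genes():
        for t in g.transcripts:
            rows.append({
                "gene_id": g.id,
                "transcript_id": t.id,
                "chrom": g.chrom,
                "strand": t.strand,
                "gene_start": g.start,
                "gene_end": g.end,
                "transcript_start": t.start,
                "transcript_end": t.end,
                "n_exons": len(t.exons),
                "exonic_length": t.exonic_length(),
                "gene_biotype": g.biotype,
                "transcript_biotype": t.biotype,
                "source": t.source,
                "exon_chain": ";".join(f"{s}-{e}" for s, e in t.exon_chain()),
            })
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "transcript_id", "chrom", "strand", "gene_start",
            "gene_end", "transcript_start", "transcript_end", "n_exons",
            "exonic_length", "gene_biotype", "transcript_biotype", "source",
            "exon_chain",
        ],
    )
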
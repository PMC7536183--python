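"""Exon merging and per-exon mean conservation scores.

Overlapping exons are merged (interval union) before scoring so that no
base contributes to a gene's conservation summary more than once. Scores
come from a per-base track stored as sorted, non-overlapping
(start, end, score) runs per chromosome — the text BedGraph format serves
as the on-disk fixture representation. The mean over an exon is taken
either over the covered bases only (``uncovered="ignore"``, the default,
matching the mean-over-covered convention of genome-browser averaging
tools) or counting uncovered bases as zero (``uncovered="zero"``).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .model import AnnotationSet, Gene


@dataclass
class MergedExon:
    chrom: str
    start: int
    end: int
    gene_id: str
    biotype: str

    def __len__(self) -> int:
        return self.end - self.start


class ScoreTrack:
    """Per-chromosome sorted non-overlapping (start, end, score) runs."""

    def __init__(self, runs: Optional[Dict[str, List[Tuple[int, int, float]]]] = None):
        self._runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, rs in runs.items():
                self.set_runs(chrom, rs)

    def set_runs(self, chrom: str, runs: Iterable[Tuple[int, int, float]]) -> None:
        rs = sorted(runs)
        starts = np.array([r[0] for r in rs], dtype=np.int64)
        ends = np.array([r[1] for r in rs], dtype=np.int64)
        scores = np.array([r[2] for r in rs], dtype=float)
        if (starts >= ends).any():
            raise ValueError(f"{chrom}: empty or inverted run")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{chrom}: overlapping runs")
        if not np.isfinite(scores).all():
            raise ValueError(f"{chrom}: non-finite scores")
        self._runs[chrom] = (starts, ends, scores)

    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> List[Tuple[int, int, float]]:
        if chrom not in self._runs:
            return []
        s, e, v = self._runs[chrom]
        return [(int(a), int(b), float(c)) for a, b, c in zip(s, e, v)]

    def coverage_and_sum(self, chrom: str, start: int, end: int) -> Tuple[int, float]:
        """(covered bases, sum of per-base scores) over [start, end)."""
        if chrom not in self._runs:
            return 0, 0.0
        starts, ends, scores = self._runs[chrom]
        i = bisect_right(starts, start) - 1
        if i < 0 or ends[i] <= start:
            i += 1
        covered, total = 0, 0.0
        while i < len(starts) and starts[i] < end:
            lo = max(int(starts[i]), start)
            hi = min(int(ends[i]), end)
            if hi > lo:
                covered += hi - lo
                total += (hi - lo) * float(scores[i])
            i += 1
        return covered, total


def read_bedgraph(path: Union[str, Path]) -> ScoreTrack:
    """Read a 4-column text BedGraph (0-based half-open) into a ScoreTrack."""
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, score = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            runs.setdefault(chrom, []).append((start, end, score))
    return ScoreTrack(runs)


def write_bedgraph(track: ScoreTrack, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for start, end, score in track.runs(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")


def _union(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivs = sorted(intervals)
    out: List[Tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def merge_exons(gene: Gene, scope: str = "per_gene") -> List[MergedExon]:
    """Interval union of a gene's exons.

    ``per_gene`` (default) unions all exons across the gene's transcripts;
    ``per_transcript`` unions within each transcript separately, so the
    same base may appear in several merged exons of different transcripts.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.id} has no transcripts")
    if scope == "per_gene":
        ivs = _union(
            (e.start, e.end) for t in gene.transcripts for e in t.exons
        )
        return [
            MergedExon(gene.chrom, s, e, gene.id, gene.biotype) for s, e in ivs
        ]
    if scope == "per_transcript":
        out: List[MergedExon] = []
        for t in sorted(gene.transcripts, key=lambda t: t.id):
            for s, e in _union((x.start, x.end) for x in t.exons):
                out.append(MergedExon(gene.chrom, s, e, gene.id, gene.biotype))
        return out
    raise ValueError(f"unknown scope {scope!r}")


def mean_score(
    exon: MergedExon, track: ScoreTrack, uncovered: str = "ignore"
) -> float:
    """Mean per-base score over a merged exon.

    ``ignore``: mean over covered bases only (NaN if fully uncovered);
    ``zero``: uncovered bases count as score 0.
    """
    covered, total = track.coverage_and_sum(exon.chrom, exon.start, exon.end)
    if uncovered == "ignore":
        return total / covered if covered else math.nan
    if uncovered == "zero":
        return total / len(exon)
    raise ValueError(f"unknown uncovered policy {uncovered!r}")


def conservation_table(
    aset: AnnotationSet,
    track: ScoreTrack,
    scope: str = "per_gene",
    uncovered: str = "ignore",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-merged-exon mean scores plus a per-biotype distribution summary.

    Rows with chromosomes absent from the track (or fully uncovered exons
    in ``ignore`` mode) carry NaN means and are flagged ``missing``.
    """
    rows = []
    for g in aset.genes():
        for i, ex in enumerate(merge_exons(g, scope=scope)):
            m = mean_score(ex, track, uncovered=uncovered)
            rows.append({
                "gene_id": g.id,
                "exon": f"{g.id}.me{i + 1}",
                "chrom": ex.chrom,
                "start": ex.start,
                "end": ex.end,
                "biotype": ex.biotype,
                "mean_score": m,
                "missing": not np.isfinite(m),
            })
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "exon", "chrom", "start", "end", "biotype",
            "mean_score", "missing",
        ],
    )
    if table.empty:
        return table, pd.DataFrame()
    summ = (
        table.dropna(subset=["mean_score"])
        .groupby("biotype")["mean_score"]
        .describe(percentiles=[0.25, 0.5, 0.75])
    )
    return table, summ


def merged_exons_bed(aset: AnnotationSet, path: Union[str, Path],
                     scope: str = "per_gene") -> None:
    """Write merged exons as BED6 (name = gene id, score = 0)."""
    with open(path, "w") as fh:
        for g in aset.genes():
            for ex in merge_exons(g, scope=scope):
                fh.write(
                    f"{ex.chrom}\t{ex.start}\t{ex.end}\t{ex.gene_id}\t0\t{g.strand}\n"
                )
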
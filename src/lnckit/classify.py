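"""Rule-based positional classification of lncRNA transcripts.

Each candidate lncRNA transcript is compared with reference RNA partner
transcripts. A pair whose spans share at least one base is GENIC, split by

* direction — sense (equal strands) or antisense,
* location — exonic (some exon-exon overlap) or intronic,
* subtype — nested (lncRNA inside the partner span), containing (partner
  inside the lncRNA) or overlapping (partial); identical spans count as
  nested.

A pair with disjoint spans within the search window is INTERGENIC, split by

* side — upstream/downstream: where the partner sits relative to the
  lncRNA's 5′ end,
* orientation — same_strand for equal strands; for opposite strands,
  divergent when the 5′ ends face each other (head-to-head; the partner is
  then necessarily on the lncRNA's 5′, i.e. upstream, side) and convergent
  when the 3′ ends face each other (tail-to-tail, downstream).

Before classification, candidates shorter than 200 bp of summed exon
length are removed, as are candidates whose same-strand exonic overlap
with reference protein-coding exons exceeds 75% of their own exonic
length (such transcripts are likely unannotated coding isoforms, not
lncRNA). Monoexonic transcripts are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .model import AnnotationSet, Transcript

GENIC = "genic"
INTERGENIC = "intergenic"

GENIC_ROWS = ["antisense_exonic", "antisense_intronic", "sense_exonic", "sense_intronic"]
GENIC_COLS = ["overlapping", "containing", "nested"]
INTERGENIC_ROWS = ["upstream", "downstream"]
INTERGENIC_COLS = ["convergent", "divergent", "same_strand"]


@dataclass
class ClassifierConfig:
    window_min: int = 10_000
    window_max: int = 100_000
    min_size: int = 200
    sense_overlap_fraction: float = 0.75
    #: report only intergenic partners with gap >= window_min (the
    #: strict-band reading); default reports every partner within window_max
    strict_band: bool = False

    def __post_init__(self) -> None:
        if self.window_min > self.window_max:
            raise ValueError("window_min must be <= window_max")
        if not (0 < self.sense_overlap_fraction <= 1):
            raise ValueError("sense_overlap_fraction must lie in (0, 1]")


@dataclass
class ClassificationRecord:
    lnc_transcript_id: str
    partner_transcript_id: str
    type: str  # GENIC | INTERGENIC
    direction: str  # sense/antisense (genic) or upstream/downstream (intergenic)
    location: str  # exonic/intronic (genic) or divergent/convergent/same_strand
    subtype: Optional[str] = None  # overlapping/containing/nested (genic only)
    distance: Optional[int] = None  # bp gap (intergenic only)
    is_best_partner: bool = False

    def cell(self) -> Tuple[str, str]:
        """(row, column) of the classification count grid."""
        if self.type == GENIC:
            return f"{self.direction}_{self.location}", self.subtype or ""
        return self.direction, self.location


def _union(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivs = sorted(ivs)
    out: List[Tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_len(a: List[Tuple[int, int]], b: List[Tuple[int, int]]) -> int:
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _is_protein_coding(t: Transcript, gene_biotype: str) -> bool:
    return t.biotype == "protein_coding" or (
        t.biotype == "other" and gene_biotype == "protein_coding"
    )


def prefilter(
    candidates: Sequence[Transcript],
    reference: AnnotationSet,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> Tuple[List[Transcript], List[Transcript], List[Transcript]]:
    """Size and sense-overlap pre-filters.

    Returns (kept, removed_short, removed_sense_overlap). The overlap rule
    applies in sense only: the same-strand exonic overlap with reference
    protein-coding exons must exceed ``sense_overlap_fraction`` of the
    candidate's own exonic length for removal; antisense overlap never
    removes a candidate.
    """
    pcg_exons: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for g in reference.genes():
        for t in g.transcripts:
            if _is_protein_coding(t, g.biotype):
                key = (t.chrom, t.strand)
                pcg_exons.setdefault(key, []).extend(
                    (e.start, e.end) for e in t.exons
                )
    pcg_exons = {k: _union(v) for k, v in pcg_exons.items()}

    kept, removed_short, removed_sense = [], [], []
    for t in candidates:
        size = t.exonic_length()
        if size < cfg.min_size:
            removed_short.append(t)
            continue
        own = _union([(e.start, e.end) for e in t.exons])
        sense = pcg_exons.get((t.chrom, t.strand), [])
        frac = _overlap_len(own, sense) / size
        if frac > cfg.sense_overlap_fraction:
            removed_sense.append(t)
            continue
        kept.append(t)
    return kept, removed_short, removed_sense


def classify_genic(lnc: Transcript, partner: Transcript) -> ClassificationRecord:
    """Classify an overlapping (lncRNA, partner) pair."""
    if lnc.chrom != partner.chrom:
        raise ValueError(
            f"{lnc.id} ({lnc.chrom}) and {partner.id} ({partner.chrom}) "
            "are on different chromosomes"
        )
    if lnc.end <= partner.start or partner.end <= lnc.start:
        raise ValueError(f"{lnc.id} and {partner.id} do not overlap; not genic")
    direction = "sense" if lnc.strand == partner.strand else "antisense"
    lnc_ex = _union([(e.start, e.end) for e in lnc.exons])
    par_ex = _union([(e.start, e.end) for e in partner.exons])
    location = "exonic" if _overlap_len(lnc_ex, par_ex) > 0 else "intronic"
    if partner.start <= lnc.start and lnc.end <= partner.end:
        subtype = "nested"  # identical spans fall here by the tie rule
    elif lnc.start <= partner.start and partner.end <= lnc.end:
        subtype = "containing"
    else:
        subtype = "overlapping"
    return ClassificationRecord(
        lnc.id, partner.id, GENIC, direction, location, subtype=subtype
    )


def classify_intergenic(
    lnc: Transcript,
    partner: Transcript,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ClassificationRecord:
    """Classify a disjoint (lncRNA, partner) pair within the window."""
    if lnc.chrom != partner.chrom:
        raise ValueError(
            f"{lnc.id} and {partner.id} are on different chromosomes"
        )
    if not (lnc.end <= partner.start or partner.end <= lnc.start):
        raise ValueError(f"{lnc.id} and {partner.id} overlap; must be genic")
    if partner.end <= lnc.start:
        gap = lnc.start - partner.end
        partner_left = True
    else:
        gap = partner.start - lnc.end
        partner_left = False
    # 5' of the lncRNA is its left end on + (or unknown) strand, right on -
    five_prime_left = lnc.strand != "-"
    partner_on_5prime = partner_left == five_prime_left
    direction = "upstream" if partner_on_5prime else "downstream"
    if lnc.strand == partner.strand:
        orientation = "same_strand"
    elif partner_on_5prime:
        orientation = "divergent"  # 5' ends face each other: head-to-head
    else:
        orientation = "convergent"  # 3' ends face each other: tail-to-tail
    return ClassificationRecord(
        lnc.id, partner.id, INTERGENIC, direction, orientation, distance=gap
    )


def _best_key(rec: ClassificationRecord, lnc: Transcript,
              partners: Dict[str, Transcript]) -> tuple:
    """Sort key: smallest wins. Genic beats intergenic; genic ranked by
    exonic overlap then span overlap then id; intergenic by distance then id."""
    p = partners[rec.partner_transcript_id]
    if rec.type == GENIC:
        lnc_ex = _union([(e.start, e.end) for e in lnc.exons])
        par_ex = _union([(e.start, e.end) for e in p.exons])
        exonic = _overlap_len(lnc_ex, par_ex)
        span = min(lnc.end, p.end) - max(lnc.start, p.start)
        return (0, -exonic, -span, rec.partner_transcript_id)
    return (1, rec.distance, rec.partner_transcript_id)


def classify_all(
    candidates: Sequence[Transcript],
    reference: AnnotationSet,
    cfg: ClassifierConfig = ClassifierConfig(),
    count_best_only: bool = False,
) -> Tuple[List[ClassificationRecord], List[str], Dict[str, pd.DataFrame]]:
    """Classify every candidate against every reference partner in window.

    Returns (records, unclassified lncRNA ids, count matrices). All genic
    interactions are reported, plus all intergenic interactions with gap
    ≤ ``window_max`` (and ≥ ``window_min`` when ``strict_band``). Exactly
    one record per classified lncRNA carries ``is_best_partner``. The count
    matrices mirror the classification grid — genic direction×location rows
    by subtype columns, and intergenic side rows by orientation columns —
    over all records (or best-partner records only with
    ``count_best_only``).
    """
    partners: Dict[str, Transcript] = {}
    trees: Dict[str, IntervalTree] = {}
    for g in reference.genes():
        for t in g.transcripts:
            partners[t.id] = t
            trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.id)

    records: List[ClassificationRecord] = []
    unclassified: List[str] = []
    for lnc in sorted(candidates, key=lambda t: t.id):
        tree = trees.get(lnc.chrom)
        mine: List[ClassificationRecord] = []
        if tree is not None:
            # pad by one base so a partner at exactly window_max gap is hit
            lo = max(0, lnc.start - cfg.window_max - 1)
            hi = lnc.end + cfg.window_max + 1
            for iv in sorted(tree.overlap(lo, hi), key=lambda iv: iv.data):
                p = partners[iv.data]
                if p.id == lnc.id:
                    continue
                if lnc.end > p.start and p.end > lnc.start:
                    mine.append(classify_genic(lnc, p))
                else:
                    rec = classify_intergenic(lnc, p, cfg)
                    if rec.distance > cfg.window_max:
                        continue
                    if cfg.strict_band and rec.distance < cfg.window_min:
                        continue
                    mine.append(rec)
        if not mine:
            unclassified.append(lnc.id)
            continue
        best = min(mine, key=lambda r: _best_key(r, lnc, partners))
        best.is_best_partner = True
        records.extend(mine)

    counted = [r for r in records if r.is_best_partner] if count_best_only else records
    genic = pd.DataFrame(0, index=GENIC_ROWS, columns=GENIC_COLS, dtype=int)
    inter = pd.DataFrame(0, index=INTERGENIC_ROWS, columns=INTERGENIC_COLS, dtype=int)
    for r in counted:
        row, col = r.cell()
        if r.type == GENIC:
            genic.loc[row, col] += 1
        else:
            inter.loc[row, col] += 1
    return records, unclassified, {"genic": genic, "intergenic": inter}


def records_table(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    rows = [
        {
            "lnc_transcript_id": r.lnc_transcript_id,
            "partner_transcript_id": r.partner_transcript_id,
            "type": r.type,
            "direction": r.direction,
            "location": r.location,
            "subtype": r.subtype or "",
            "distance": "" if r.distance is None else r.distance,
            "is_best_partner": r.is_best_partner,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lnc_transcript_id", "partner_transcript_id", "type", "direction",
            "location", "subtype", "distance", "is_best_partner",
        ],
    )
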
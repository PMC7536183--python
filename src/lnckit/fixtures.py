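"""Synthetic fixtures with recorded ground truth.

Everything the toolkit consumes — multi-source overlapping gene models,
tissue-structured count matrices, per-base score tracks — can be generated
on short synthetic contigs (≤ 10⁶ bp, so brute-force per-base oracles stay
feasible). Every generator is a pure function of a :class:`FixtureSpec`
seed: the same spec yields bit-identical output, and the returned
:class:`GroundTruth` records the intended fate/class/tissue of every
planted record so module outputs can be checked exactly.

`labelled_merge_scenario` builds, by hand, the canonical two-annotation
merge scenario with one enclosed gene (transcripts: one out-of-bounds, two
admissible), one partially overlapping gene (discarded whole) and one
disjoint gene (added with both transcripts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conservation import ScoreTrack
from .model import AnnotationSet, Exon, Gene, Transcript
from .specificity import ExpressionMatrix

CONTIG_LEN = 1_000_000
CONTIGS = ("chrS1", "chrS2", "chrS3", "chrS4")

GENIC_CLASSES = [
    f"genic:{d}:{loc}:{sub}"
    for d in ("sense", "antisense")
    for loc in ("exonic", "intronic")
    for sub in ("overlapping", "containing", "nested")
]
INTERGENIC_CLASSES = [
    "intergenic:upstream:divergent",
    "intergenic:upstream:same_strand",
    "intergenic:downstream:convergent",
    "intergenic:downstream:same_strand",
]
ALL_CLASSES = GENIC_CLASSES + INTERGENIC_CLASSES


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 100
    n_sources: int = 3
    n_tissues: int = 31
    replicates_per_tissue: int = 3
    #: proportions of candidate genes engineered enclosed / partial / disjoint
    overlap_mix: Tuple[float, float, float] = (0.4, 0.2, 0.4)
    planted_specific_fraction: float = 0.2
    #: proportions over the positional classes; None = uniform over ALL_CLASSES
    class_mix: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if abs(sum(self.overlap_mix) - 1.0) > 1e-9:
            raise ValueError("overlap_mix must sum to 1")
        if self.class_mix is not None:
            if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
                raise ValueError("class_mix must sum to 1")
            unknown = set(self.class_mix) - set(ALL_CLASSES)
            if unknown:
                raise ValueError(f"unknown classes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    #: candidate gene id -> intended overlap category {enclosed,partial,disjoint}
    gene_category: Dict[str, str] = field(default_factory=dict)
    #: candidate transcript id -> intended merge fate
    transcript_fate: Dict[str, str] = field(default_factory=dict)
    #: gene id -> planted specific tissue (absent for ubiquitous genes)
    specific_tissue: Dict[str, str] = field(default_factory=dict)
    #: lnc transcript id -> (intended partner transcript id, class label)
    intended_class: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    #: gene id -> gene-level source membership after the intended merge
    gene_sources: Dict[str, frozenset] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

def _make_transcript(
    tid: str, gid: str, source: str, chrom: str, strand: str,
    span: Tuple[int, int], rng: np.random.Generator,
    n_exons: Optional[int] = None, biotype: str = "lncRNA",
) -> Transcript:
    start, end = span
    if n_exons is None:
        n_exons = int(rng.integers(1, 5))
    n_exons = min(n_exons, max(1, (end - start) // 200))
    t = Transcript(tid, gid, source, biotype=biotype)
    if n_exons == 1:
        bounds = [start, end]
    else:
        inner = np.sort(rng.choice(
            np.arange(start + 50, end - 50), size=2 * (n_exons - 1), replace=False,
        ))
        bounds = [start, *inner.tolist(), end]
    for i in range(n_exons):
        s, e = int(bounds[2 * i]), int(bounds[2 * i + 1])
        if e <= s:
            e = s + 1
        t.exons.append(Exon(chrom, s, e, strand, tid))
    t.normalize()
    return t


def _fill_gene(
    gene: Gene, source: str, rng: np.random.Generator,
    n_transcripts: Optional[int] = None, biotype: str = "lncRNA",
) -> None:
    if n_transcripts is None:
        n_transcripts = int(rng.integers(1, 4))
    for j in range(n_transcripts):
        lo = int(rng.integers(gene.start, gene.start + max(1, len(gene) // 4)))
        hi = int(rng.integers(gene.end - max(1, len(gene) // 4), gene.end)) + 1
        hi = min(hi, gene.end)
        if hi - lo < 100:
            lo, hi = gene.start, gene.end
        t = _make_transcript(
            f"{gene.id}.t{j + 1}", gene.id, source, gene.chrom, gene.strand,
            (lo, hi), rng, biotype=biotype,
        )
        gene.transcripts.append(t)


class _SlotAllocator:
    """Dole out disjoint genomic slots across the synthetic contigs."""

    def __init__(self, slot: int = 10_000, gap: int = 2_000):
        self.slot, self.gap = slot, gap
        self.idx = 0
        per_contig = CONTIG_LEN // (slot + gap)
        self.per_contig = per_contig
        self.capacity = per_contig * len(CONTIGS)

    def take(self) -> Tuple[str, int, int]:
        if self.idx >= self.capacity:
            raise ValueError("fixture ran out of genomic slots; lower n_genes")
        chrom = CONTIGS[self.idx // self.per_contig]
        k = self.idx % self.per_contig
        self.idx += 1
        start = k * (self.slot + self.gap) + self.gap
        return chrom, start, start + self.slot


def gen_annotations(
    spec: FixtureSpec,
) -> Tuple[AnnotationSet, List[AnnotationSet], GroundTruth]:
    """Reference plus candidate annotation sets with planted merge fates.

    Candidate genes are engineered enclosed / partially overlapping /
    disjoint with respect to the reference in the requested proportions.
    Enclosed genes may additionally carry a planted duplicate transcript
    (copy of a reference exon chain) and a planted out-of-bounds
    transcript (span escaping the reference gene boundary).
    """
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    alloc = _SlotAllocator()

    n_cand = spec.n_genes
    n_enc = round(spec.overlap_mix[0] * n_cand)
    n_par = round(spec.overlap_mix[1] * n_cand)
    n_dis = n_cand - n_enc - n_par
    for frac, count, label in zip(
        spec.overlap_mix, (n_enc, n_par, n_dis), ("enclosed", "partial", "disjoint")
    ):
        if frac > 0 and count == 0:
            raise ValueError(
                f"overlap_mix requests {label} candidates but n_genes={n_cand} "
                "is too small to realize the proportion"
            )

    n_ref = max(n_enc, 10)
    reference = AnnotationSet("ref")
    ref_genes: List[Gene] = []
    for i in range(n_ref):
        chrom, lo, hi = alloc.take()
        start = lo + int(rng.integers(0, 2000))
        end = hi - int(rng.integers(0, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "protein_coding" if rng.random() < 0.5 else "lncRNA"
        g = Gene(f"ref_g{i + 1:04d}", chrom, strand, start, end, biotype)
        _fill_gene(g, "ref", rng, biotype=biotype)
        reference.add_gene(g)
        ref_genes.append(g)

    candidates: List[AnnotationSet] = []
    n_cand_sources = max(1, spec.n_sources - 1)
    for s in range(n_cand_sources):
        src = f"src{s + 1}"
        cand = AnnotationSet(src)
        cats = (["enclosed"] * n_enc + ["partial"] * n_par + ["disjoint"] * n_dis)
        rng.shuffle(cats)
        for i, cat in enumerate(cats):
            gid = f"{src}_g{i + 1:04d}"
            if cat == "enclosed":
                host = ref_genes[int(rng.integers(0, len(ref_genes)))]
                pad = max(50, len(host) // 10)
                gs = host.start + int(rng.integers(0, pad))
                ge = host.end - int(rng.integers(0, pad))
                strand = host.strand if rng.random() < 0.7 else (
                    "-" if host.strand == "+" else "+")
                g = Gene(gid, host.chrom, strand, gs, ge, "lncRNA")
                _fill_gene(g, src, rng)
                for t in g.transcripts:
                    truth.transcript_fate[t.id] = "added"
                if rng.random() < 0.4 and host.transcripts:
                    # planted duplicate: exact copy of a reference exon chain
                    ht = host.transcripts[int(rng.integers(0, len(host.transcripts)))]
                    dup = Transcript(f"{gid}.dup", gid, src, biotype="lncRNA")
                    dup.exons = [
                        Exon(e.chrom, e.start, e.end, e.strand, dup.id)
                        for e in ht.exons
                    ]
                    g.transcripts.append(dup)
                    truth.transcript_fate[dup.id] = "duplicate_skipped"
                if rng.random() < 0.4:
                    # planted escapee: span extends past the host boundary
                    oob = _make_transcript(
                        f"{gid}.oob", gid, src, host.chrom, strand,
                        (host.end - 200, host.end + 500), rng, n_exons=1,
                    )
                    g.transcripts.append(oob)
                    truth.transcript_fate[oob.id] = "discarded_out_of_bounds"
            elif cat == "partial":
                host = ref_genes[int(rng.integers(0, len(ref_genes)))]
                gs = max(0, host.start - int(rng.integers(500, 3000)))
                ge = host.start + max(100, len(host) // 3)
                strand = "+" if rng.random() < 0.5 else "-"
                g = Gene(gid, host.chrom, strand, gs, ge, "lncRNA")
                _fill_gene(g, src, rng)
                for t in g.transcripts:
                    truth.transcript_fate[t.id] = "discarded_with_partial_gene"
            else:  # disjoint
                chrom, lo, hi = alloc.take()
                gs = lo + int(rng.integers(0, 2000))
                ge = hi - int(rng.integers(0, 2000))
                strand = "+" if rng.random() < 0.5 else "-"
                g = Gene(gid, chrom, strand, gs, ge, "lncRNA")
                _fill_gene(g, src, rng)
                for t in g.transcripts:
                    truth.transcript_fate[t.id] = "added"
            truth.gene_category[gid] = cat
            cand.add_gene(g)
        candidates.append(cand)
    return reference, candidates, truth


def labelled_merge_scenario() -> Tuple[AnnotationSet, AnnotationSet]:
    """Hand-built two-annotation merge scenario covering every labelled case.

    Reference (2 genes) vs candidate with: ``cand_g1`` enclosed in
    ``ref_gA`` carrying transcripts ``t1.1`` (escapes the reference gene
    boundary → discarded), ``t1.2`` and ``t1.3`` (novel chains → admitted);
    ``cand_g2`` straddling ``ref_gB``'s boundary (whole gene discarded,
    transcript ``t2.1`` with it); ``cand_g3`` disjoint from everything
    (added as a new lncRNA gene with ``t3.1`` and ``t3.2``).
    """
    ref = AnnotationSet("ref")
    gA = Gene("ref_gA", "chrS1", "+", 10_000, 20_000, "protein_coding")
    tA = Transcript("ref_tA", "ref_gA", "ref", biotype="protein_coding")
    tA.exons = [
        Exon("chrS1", 10_000, 12_000, "+", "ref_tA"),
        Exon("chrS1", 15_000, 20_000, "+", "ref_tA"),
    ]
    gA.transcripts.append(tA)
    gB = Gene("ref_gB", "chrS1", "-", 40_000, 50_000, "protein_coding")
    tB = Transcript("ref_tB", "ref_gB", "ref", biotype="protein_coding")
    tB.exons = [Exon("chrS1", 40_000, 50_000, "-", "ref_tB")]
    gB.transcripts.append(tB)
    ref.add_gene(gA)
    ref.add_gene(gB)

    cand = AnnotationSet("cand")
    g1 = Gene("cand_g1", "chrS1", "+", 11_000, 19_000, "lncRNA")
    t11 = Transcript("t1.1", "cand_g1", "cand", biotype="lncRNA")
    t11.exons = [Exon("chrS1", 18_000, 22_000, "+", "t1.1")]  # escapes ref_gA
    t12 = Transcript("t1.2", "cand_g1", "cand", biotype="lncRNA")
    t12.exons = [
        Exon("chrS1", 11_000, 11_500, "+", "t1.2"),
        Exon("chrS1", 13_000, 14_000, "+", "t1.2"),
    ]
    t13 = Transcript("t1.3", "cand_g1", "cand", biotype="lncRNA")
    t13.exons = [Exon("chrS1", 16_000, 18_500, "+", "t1.3")]
    g1.transcripts += [t11, t12, t13]

    g2 = Gene("cand_g2", "chrS1", "-", 35_000, 45_000, "lncRNA")
    t21 = Transcript("t2.1", "cand_g2", "cand", biotype="lncRNA")
    t21.exons = [Exon("chrS1", 35_000, 45_000, "-", "t2.1")]
    g2.transcripts.append(t21)

    g3 = Gene("cand_g3", "chrS1", "+", 70_000, 80_000, "lncRNA")
    t31 = Transcript("t3.1", "cand_g3", "cand", biotype="lncRNA")
    t31.exons = [
        Exon("chrS1", 70_000, 72_000, "+", "t3.1"),
        Exon("chrS1", 75_000, 80_000, "+", "t3.1"),
    ]
    t32 = Transcript("t3.2", "cand_g3", "cand", biotype="lncRNA")
    t32.exons = [Exon("chrS1", 71_000, 78_000, "+", "t3.2")]
    g3.transcripts += [t31, t32]

    for g in (g1, g2, g3):
        cand.add_gene(g)
    return ref, cand


# ---------------------------------------------------------------------------
# expression fixtures
# ---------------------------------------------------------------------------

def gen_expression(
    spec: FixtureSpec,
) -> Tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Negative-binomial counts with planted tissue-specific genes.

    Ubiquitous genes share one mean across tissues; planted specific genes
    are near-silent outside one randomly chosen tissue where their mean is
    boosted ~200-fold. Gene lengths and biotypes are attached so the same
    fixture feeds TPM normalization and the expression filters.
    """
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    tissues = [f"T{i + 1:02d}" for i in range(spec.n_tissues)]
    samples, tissue_of = [], {}
    for t in tissues:
        for r in range(spec.replicates_per_tissue):
            sid = f"{t}_r{r + 1}"
            samples.append(sid)
            tissue_of[sid] = t

    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    lengths = rng.integers(500, 5001, size=spec.n_genes)
    biotypes = np.where(rng.random(spec.n_genes) < 0.5, "protein_coding", "lncRNA")
    n_spec = round(spec.planted_specific_fraction * spec.n_genes)
    specific_idx = rng.choice(spec.n_genes, size=n_spec, replace=False)

    mean = np.empty((spec.n_genes, spec.n_tissues))
    base = rng.lognormal(mean=np.log(30.0), sigma=1.0, size=spec.n_genes)
    for i in range(spec.n_genes):
        mean[i, :] = base[i]
    for i in specific_idx:
        t_idx = int(rng.integers(0, spec.n_tissues))
        mean[i, :] = 1.0
        mean[i, t_idx] = 200.0 * (1.0 + rng.random())
        truth.specific_tissue[genes[i]] = tissues[t_idx]

    disp = 10.0  # NB size parameter; variance = m + m^2/disp
    counts = np.empty((spec.n_genes, len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        t_idx = tissues.index(tissue_of[sid])
        m = mean[:, t_idx] * rng.uniform(0.85, 1.15)  # library-depth wobble
        counts[:, j] = rng.negative_binomial(disp, disp / (disp + m))

    values = pd.DataFrame(counts, index=genes, columns=samples)
    gene_meta = pd.DataFrame(
        {"length": lengths, "biotype": biotypes}, index=genes
    )
    tissue_map = pd.Series(tissue_of, name="tissue")
    em = ExpressionMatrix(values.astype(float), tissue_map, gene_meta)
    return em, tissue_map, truth


# ---------------------------------------------------------------------------
# score-track fixtures
# ---------------------------------------------------------------------------

def gen_score_track(
    spec: FixtureSpec,
    high_regions: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    run_len: int = 500,
    coverage: float = 0.8,
) -> ScoreTrack:
    """Piecewise-constant random score runs over the fixture contigs.

    Scores are uniform in [0, 0.3]; ``high_regions`` intervals are overlaid
    with runs scoring in [0.8, 1.0]. A ``coverage`` fraction < 1 leaves
    random gaps so the uncovered-base policies are exercised.
    """
    rng = np.random.default_rng(spec.seed + 7)
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    for chrom in CONTIGS:
        rs = []
        pos = 0
        while pos < CONTIG_LEN:
            length = int(rng.integers(run_len // 2, run_len * 2))
            end = min(pos + length, CONTIG_LEN)
            if rng.random() < coverage:
                rs.append((pos, end, float(np.round(rng.uniform(0.0, 0.3), 4))))
            pos = end
        runs[chrom] = rs
    track = ScoreTrack(runs)
    if high_regions:
        merged: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom in CONTIGS:
            high = sorted(high_regions.get(chrom, []))
            out: List[Tuple[int, int, float]] = []
            for s, e, v in track.runs(chrom):
                pieces = [(s, e, v)]
                for hs, he in high:
                    nxt = []
                    for (ps, pe, pv) in pieces:
                        if he <= ps or pe <= hs:
                            nxt.append((ps, pe, pv))
                        else:
                            if ps < hs:
                                nxt.append((ps, hs, pv))
                            if he < pe:
                                nxt.append((he, pe, pv))
                    pieces = nxt
                out.extend(pieces)
            for hs, he in high:
                out.append((hs, he, float(np.round(rng.uniform(0.8, 1.0), 4))))
            merged[chrom] = sorted(out)
        track = ScoreTrack(merged)
    return track


def planted_conservation_fixture(
    spec: FixtureSpec,
) -> Tuple[AnnotationSet, ScoreTrack]:
    """Annotation set whose protein-coding exons sit on high-score runs."""
    reference, _, _ = gen_annotations(spec)
    high: Dict[str, List[Tuple[int, int]]] = {}
    for g in reference.genes():
        if g.biotype == "protein_coding":
            for t in g.transcripts:
                for e in t.exons:
                    high.setdefault(g.chrom, []).append((e.start, e.end))
    for chrom in list(high):
        merged: List[Tuple[int, int]] = []
        for s, e in sorted(high[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        high[chrom] = merged
    return reference, gen_score_track(spec, high_regions=high)


# ---------------------------------------------------------------------------
# classification fixtures
# ---------------------------------------------------------------------------

def _partner(tid: str, chrom: str, strand: str, s: int) -> Transcript:
    """mRNA partner: two exons (s, s+1000) and (s+4000, s+5000)."""
    t = Transcript(tid, tid, "ref", biotype="protein_coding")
    t.exons = [
        Exon(chrom, s, s + 1000, strand, tid),
        Exon(chrom, s + 4000, s + 5000, strand, tid),
    ]
    return t


def _planted_lnc(
    label: str, tid: str, chrom: str, pstrand: str, s: int
) -> Transcript:
    """Build a lncRNA realizing ``label`` against the partner at ``s``."""
    kind = label.split(":")
    if kind[0] == "genic":
        _, direction, location, subtype = kind
        strand = pstrand if direction == "sense" else ("-" if pstrand == "+" else "+")
        t = Transcript(tid, tid, "cand", biotype="lncRNA")
        if subtype == "nested":
            if location == "exonic":
                ivs = [(s + 500, s + 1500)]
            else:
                ivs = [(s + 1500, s + 2500)]
        elif subtype == "containing":
            if location == "exonic":
                ivs = [(s - 500, s + 5500)]
            else:  # span contains the partner, exons dodge its exons
                ivs = [(s - 500, s - 100), (s + 2000, s + 2500), (s + 5100, s + 5500)]
        else:  # overlapping: crosses the partner's right boundary
            if location == "exonic":
                ivs = [(s + 4500, s + 6000)]
            else:
                ivs = [(s + 2000, s + 2400), (s + 5100, s + 6000)]
        for lo, hi in ivs:
            t.exons.append(Exon(chrom, lo, hi, strand, tid))
        t.normalize()
        return t
    # intergenic
    _, side, orientation = kind
    gap = 15_000
    if side == "upstream":
        # partner must sit on the lncRNA's 5' side
        if orientation == "same_strand":
            strand = pstrand
        else:  # divergent: opposite strands, head-to-head
            strand = "-" if pstrand == "+" else "+"
        # choose lnc strand first, then place partner 5' of it
        lnc_strand = strand
        if lnc_strand == "+":
            lo = s + 5000 + gap
        else:
            lo = s - gap - 2000
    else:  # downstream
        if orientation == "same_strand":
            strand = pstrand
        else:  # convergent: opposite strands, tail-to-tail
            strand = "-" if pstrand == "+" else "+"
        lnc_strand = strand
        if lnc_strand == "+":
            lo = s - gap - 2000
        else:
            lo = s + 5000 + gap
    t = Transcript(tid, tid, "cand", biotype="lncRNA")
    t.exons = [Exon(chrom, lo, lo + 2000, lnc_strand, tid)]
    return t


def gen_classification(
    spec: FixtureSpec,
) -> Tuple[List[Transcript], AnnotationSet, GroundTruth]:
    """Isolated (lncRNA, mRNA-partner) pairs realizing planted classes.

    Each pair occupies its own genomic neighbourhood, far beyond the
    classifier search window from every other pair, so the planted class
    is the only possible record for that lncRNA.
    """
    rng = np.random.default_rng(spec.seed + 13)
    if spec.class_mix is None:
        mix = {c: 1.0 / len(ALL_CLASSES) for c in ALL_CLASSES}
    else:
        mix = spec.class_mix
    labels: List[str] = []
    classes = sorted(mix)
    n_each = {c: round(mix[c] * spec.n_genes) for c in classes}
    for c in classes:
        labels += [c] * n_each[c]
    rng.shuffle(labels)

    truth = GroundTruth()
    reference = AnnotationSet("ref")
    candidates: List[Transcript] = []
    spacing = 250_000  # > window_max + pair extent
    pairs_per_contig = CONTIG_LEN // spacing
    for i, label in enumerate(labels):
        # classification pairs get their own contig series so any number of
        # isolated neighbourhoods fits
        chrom = f"chrC{i // pairs_per_contig + 1}"
        base = (i % pairs_per_contig) * spacing + 60_000
        pstrand = "+" if rng.random() < 0.5 else "-"
        pid = f"mRNA_{i + 1:04d}"
        partner = _partner(pid, chrom, pstrand, base)
        pg = Gene(pid, chrom, pstrand, partner.start, partner.end,
                  "protein_coding", transcripts=[partner])
        partner.gene_id = pid
        reference.add_gene(pg)
        lid = f"lnc_{i + 1:04d}"
        lnc = _planted_lnc(label, lid, chrom, pstrand, base)
        candidates.append(lnc)
        truth.intended_class[lid] = (pid, label)
    return candidates, reference, truth
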
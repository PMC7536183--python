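import numpy as np
import pytest

from lnckit import fixtures as fx
from lnckit.model import AnnotationSet, Exon, Gene, Transcript


@pytest.fixture
def labelled_scenario():
    """Two-annotation merge scenario covering every labelled overlap case."""
    return fx.labelled_merge_scenario()


@pytest.fixture
def small_spec():
    return fx.FixtureSpec(seed=11, n_genes=60)


def make_transcript(tid, chrom, strand, exons, gene_id=None, source="t",
                    biotype="lncRNA"):
    t = Transcript(tid, gene_id or tid, source, biotype=biotype)
    t.exons = [Exon(chrom, s, e, strand, tid) for s, e in exons]
    t.normalize()
    return t


def make_gene(gid, chrom, strand, start, end, biotype="lncRNA", transcripts=()):
    return Gene(gid, chrom, strand, start, end, biotype, list(transcripts))


def single_gene_set(name, gene):
    aset = AnnotationSet(name)
    aset.add_gene(gene)
    return aset


def random_transcripts(rng, chrom, n, lo=0, hi=500_000, biotype="lncRNA",
                       prefix="t", source="rand"):
    """Random multi-exon transcripts for oracle-equivalence fixtures."""
    out = []
    for i in range(n):
        start = int(rng.integers(lo, hi - 20_000))
        length = int(rng.integers(300, 15_000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        tid = f"{prefix}{i + 1:03d}"
        if n_ex == 1 or length < 900:
            exons = [(start, start + length)]
        else:
            cuts = np.sort(rng.choice(
                np.arange(start + 100, start + length - 100),
                size=2 * (n_ex - 1), replace=False))
            bounds = [start, *[int(c) for c in cuts], start + length]
            exons = [
                (bounds[2 * k], max(bounds[2 * k] + 1, bounds[2 * k + 1]))
                for k in range(n_ex)
            ]
        out.append(make_transcript(tid, chrom, strand, exons, source=source,
                                   biotype=biotype))
    return out
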
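import numpy as np
import pytest

import lnckit as lk
from lnckit import fixtures as fx
from lnckit.merge import (
    ADDED, ADDED_NEW, DISCARDED_OUT_OF_BOUNDS, DISCARDED_PARTIAL,
    DISCARDED_WITH_PARTIAL_GENE, DUPLICATE_SKIPPED, MERGED_INTO, OverlapClass,
    admit_transcripts, classify_gene_overlap,
)

from conftest import make_gene, make_transcript, single_gene_set


def brute_force_overlap(candidate, reference, strand_aware=False):
    """Independent all-pairs scan re-deriving the overlap class."""
    sharing, enclosing = [], []
    for g in reference.genes():
        if g.chrom != candidate.chrom:
            continue
        if strand_aware and g.strand != candidate.strand:
            continue
        if g.start < candidate.end and candidate.start < g.end:
            sharing.append(g)
            if g.start <= candidate.start and candidate.end <= g.end:
                enclosing.append(g)
    if not sharing:
        return OverlapClass.NONE
    return OverlapClass.ENCLOSED_OR_FULL if enclosing else OverlapClass.PARTIAL


def _ref_100_200():
    g = make_gene("R", "c", "+", 100, 200, transcripts=[
        make_transcript("Rt", "c", "+", [(100, 200)], gene_id="R")])
    return single_gene_set("ref", g)


class TestClassifyGeneOverlap:
    @pytest.mark.parametrize("span,expected", [
        ((120, 180), OverlapClass.ENCLOSED_OR_FULL),  # enclosed
        ((150, 250), OverlapClass.PARTIAL),           # straddles boundary
        ((300, 400), OverlapClass.NONE),              # outside
        ((100, 200), OverlapClass.ENCLOSED_OR_FULL),  # identical boundaries
        ((50, 250), OverlapClass.PARTIAL),            # encloses the reference
    ])
    def test_overlap_classes(self, span, expected):
        cand = make_gene("C", "c", "+", *span)
        cls, best = classify_gene_overlap(cand, _ref_100_200())
        assert cls is expected
        assert (best == "R") == (expected is OverlapClass.ENCLOSED_OR_FULL)

    def test_strand_aware_excludes_antisense_reference(self):
        cand = make_gene("C", "c", "-", 120, 180)
        cls, _ = classify_gene_overlap(cand, _ref_100_200(), strand_aware=True)
        assert cls is OverlapClass.NONE
        cls, _ = classify_gene_overlap(cand, _ref_100_200(), strand_aware=False)
        assert cls is OverlapClass.ENCLOSED_OR_FULL

    def test_enclosure_wins_over_partial_overlap_elsewhere(self):
        # candidate enclosed in one gene while partially overlapping another
        aset = lk.AnnotationSet("ref")
        aset.add_gene(make_gene("big", "c", "+", 0, 1000))
        aset.add_gene(make_gene("side", "c", "+", 900, 2000))
        cand = make_gene("C", "c", "+", 800, 950)
        cls, best = classify_gene_overlap(cand, aset)
        assert cls is OverlapClass.ENCLOSED_OR_FULL and best == "big"

    def test_best_gene_tie_break_smallest_span_then_id(self):
        aset = lk.AnnotationSet("ref")
        aset.add_gene(make_gene("wide", "c", "+", 0, 1000))
        aset.add_gene(make_gene("narrow", "c", "+", 100, 400))
        cand = make_gene("C", "c", "+", 150, 350)
        _, best = classify_gene_overlap(cand, aset)
        assert best == "narrow"
        aset2 = lk.AnnotationSet("ref")
        aset2.add_gene(make_gene("b", "c", "+", 0, 1000))
        aset2.add_gene(make_gene("a", "c", "+", 0, 1000))
        _, best = classify_gene_overlap(make_gene("C", "c", "+", 10, 20), aset2)
        assert best == "a"

    @pytest.mark.parametrize("strand_aware", [False, True])
    def test_agrees_with_brute_force_all_pairs(self, strand_aware):
        for seed in range(20):
            ref, cands, _ = fx.gen_annotations(
                fx.FixtureSpec(seed=seed, n_genes=40))
            for cand in cands:
                for g in cand.genes():
                    cls, _ = classify_gene_overlap(g, ref, strand_aware)
                    assert cls is brute_force_overlap(g, ref, strand_aware)


class TestAdmitTranscripts:
    def test_out_of_bounds_discarded(self):
        gene = make_gene("G", "c", "+", 100, 500)
        t = make_transcript("t", "c", "+", [(550, 700)], gene_id="x")
        _, fates = admit_transcripts(gene, [t])
        assert fates == {"t": DISCARDED_OUT_OF_BOUNDS}
        assert gene.transcripts == []

    def test_novel_chain_added_with_exons_and_source(self):
        gene = make_gene("G", "c", "+", 100, 500, transcripts=[
            make_transcript("old", "c", "+", [(100, 500)], gene_id="G")])
        t = make_transcript("new", "c", "+", [(150, 250), (300, 450)],
                            gene_id="x", source="other")
        _, fates = admit_transcripts(gene, [t])
        assert fates == {"new": ADDED}
        added = [x for x in gene.transcripts if x.id == "new"][0]
        assert added.gene_id == "G" and added.source == "other"
        assert len(added.exons) == 2
        assert gene.sources == {"t", "other"}

    def test_identical_chain_skipped(self):
        gene = make_gene("G", "c", "+", 100, 500, transcripts=[
            make_transcript("old", "c", "+", [(150, 250)], gene_id="G")])
        t = make_transcript("dup", "c", "+", [(150, 250)], gene_id="x")
        _, fates = admit_transcripts(gene, [t])
        assert fates == {"dup": DUPLICATE_SKIPPED}

    def test_chrom_mismatch_is_error(self):
        gene = make_gene("G", "c1", "+", 100, 500)
        t = make_transcript("t", "c2", "+", [(150, 250)])
        with pytest.raises(ValueError):
            admit_transcripts(gene, [t])

    def test_gene_boundary_never_changes(self):
        gene = make_gene("G", "c", "+", 100, 500)
        t = make_transcript("t", "c", "+", [(120, 480)])
        admit_transcripts(gene, [t])
        assert gene.span == (100, 500)


class TestMergePair:
    def test_labelled_scenario_fates(self, labelled_scenario):
        ref, cand = labelled_scenario
        merged, rep = lk.merge_pair(ref, cand)
        assert rep.gene_fates == {
            "cand_g1": (MERGED_INTO, "ref_gA"),
            "cand_g2": (DISCARDED_PARTIAL, None),
            "cand_g3": (ADDED_NEW, None),
        }
        assert rep.transcript_fates == {
            "t1.1": DISCARDED_OUT_OF_BOUNDS,
            "t1.2": ADDED, "t1.3": ADDED,
            "t2.1": DISCARDED_WITH_PARTIAL_GENE,
            "t3.1": ADDED, "t3.2": ADDED,
        }
        assert len(merged) == 3  # two reference genes + the new lncRNA gene
        assert merged["cand_g3"].biotype == "lncRNA"
        assert {t.id for t in merged["ref_gA"].transcripts} == {
            "ref_tA", "t1.2", "t1.3"}

    def test_self_merge_changes_no_counts(self, small_spec):
        ref, cands, _ = fx.gen_annotations(small_spec)
        merged, _ = lk.merge_all(ref, cands)
        again, rep = lk.merge_pair(merged, merged)
        assert len(again) == len(merged)
        assert again.n_transcripts() == merged.n_transcripts()
        assert again.n_exons() == merged.n_exons()
        counts = rep.transcript_counts()
        assert counts[ADDED] == 0 and counts[DISCARDED_OUT_OF_BOUNDS] == 0

    def test_disjoint_candidate_increments_gene_count(self):
        ref = _ref_100_200()
        cand = single_gene_set("c2", make_gene(
            "N", "c", "+", 300, 400, transcripts=[
                make_transcript("Nt", "c", "+", [(300, 400)], gene_id="N")]))
        merged, _ = lk.merge_pair(ref, cand)
        assert len(merged) == len(ref) + 1

    def test_fate_conservation(self, small_spec):
        ref, cands, _ = fx.gen_annotations(small_spec)
        merged = ref
        for cand in cands:
            merged, rep = lk.merge_pair(merged, cand)
            assert len(rep.gene_fates) == len(cand)
            assert len(rep.transcript_fates) == cand.n_transcripts()
            assert sum(rep.transcript_counts().values()) == cand.n_transcripts()

    def test_reference_boundaries_immutable(self, small_spec):
        ref, cands, _ = fx.gen_annotations(small_spec)
        spans = {g.id: g.span for g in ref.genes()}
        merged, _ = lk.merge_all(ref, cands)
        for gid, span in spans.items():
            assert merged[gid].span == span

    def test_gene_id_collision_suffixed_with_source(self):
        ref = _ref_100_200()
        clash = single_gene_set("src9", make_gene(
            "R", "c", "+", 300, 400, transcripts=[
                make_transcript("ct", "c", "+", [(300, 400)], gene_id="R")]))
        merged, rep = lk.merge_pair(ref, clash)
        assert rep.renamed == {"R": "R_src9"}
        assert "R_src9" in merged

    def test_every_output_transcript_within_gene_boundary(self, small_spec):
        ref, cands, _ = fx.gen_annotations(small_spec)
        merged, _ = lk.merge_all(ref, cands)
        for g in merged.genes():
            for t in g.transcripts:
                assert g.start <= t.start and t.end <= g.end


class TestMergeAll:
    def test_disjoint_sets_sum_gene_counts(self):
        sets = []
        for i in range(3):
            g = make_gene(f"g{i}", "c", "+", 1000 * i, 1000 * i + 500,
                          transcripts=[make_transcript(
                              f"t{i}", "c", "+", [(1000 * i, 1000 * i + 500)],
                              gene_id=f"g{i}")])
            sets.append(single_gene_set(f"s{i}", g))
        merged, reports = lk.merge_all(sets[0], sets[1:])
        assert len(merged) == 3
        assert len(reports) == 2

    def test_single_candidate_equals_merge_pair(self, labelled_scenario):
        ref, cand = labelled_scenario
        via_all, _ = lk.merge_all(ref, [cand])
        via_pair, _ = lk.merge_pair(ref, cand)
        assert via_all.structurally_equal(via_pair)

    def test_empty_candidate_list_returns_reference(self, labelled_scenario):
        ref, _ = labelled_scenario
        merged, reports = lk.merge_all(ref, [])
        assert merged.structurally_equal(ref) and reports == []

    def test_candidate_order_matters(self):
        # A adds a big gene outside the reference; B is enclosed by A's gene
        # but only partially overlaps the original reference gene.
        ref = _ref_100_200()
        a = single_gene_set("a", make_gene(
            "A", "c", "+", 150, 900, transcripts=[
                make_transcript("at", "c", "+", [(150, 900)], gene_id="A")]))
        b = single_gene_set("b", make_gene(
            "B", "c", "+", 400, 800, transcripts=[
                make_transcript("bt", "c", "+", [(400, 800)], gene_id="B")]))
        # order (a, b): a is PARTIAL vs ref -> discarded; b is NONE -> added
        m_ab, _ = lk.merge_all(ref, [a, b])
        # order (b, a): b NONE -> added; a still PARTIAL vs ref
        m_ba, _ = lk.merge_all(ref, [b, a])
        assert "B" in m_ab and "B" in m_ba and "A" not in m_ab
        # now make a disjoint from ref so order changes b's fate
        a2 = single_gene_set("a", make_gene(
            "A", "c", "+", 300, 900, transcripts=[
                make_transcript("at", "c", "+", [(300, 900)], gene_id="A")]))
        m1, _ = lk.merge_all(ref, [a2, b])  # b enclosed by added A
        m2, _ = lk.merge_all(ref, [b, a2])  # b added as its own gene first
        assert "B" not in m1 and "B" in m2
        assert {t.id for t in m1["A"].transcripts} == {"at", "bt"}

    def test_monotone_gene_and_transcript_counts(self, small_spec):
        ref, cands, _ = fx.gen_annotations(small_spec)
        merged = ref
        for cand in cands:
            nxt, _ = lk.merge_pair(merged, cand)
            assert len(nxt) >= len(merged)
            assert nxt.n_transcripts() >= merged.n_transcripts()
            merged = nxt


class TestContributionMatrix:
    def test_multi_source_gene_counted_once_under_its_combination(self):
        gene = make_gene("G", "c", "+", 0, 1000, transcripts=[
            make_transcript("t1", "c", "+", [(0, 100)], gene_id="G",
                            source="chess"),
            make_transcript("t2", "c", "+", [(200, 300)], gene_id="G",
                            source="noncode"),
        ])
        table, counts = lk.contribution_matrix(single_gene_set("m", gene))
        assert counts.to_dict() == {"chess&noncode": 1}
        assert table.loc[0, ["chess", "noncode"]].all()

    def test_single_source_genes_have_no_higher_order_intersections(self):
        aset = lk.AnnotationSet("m")
        for i, src in enumerate(["a", "b"]):
            aset.add_gene(make_gene(f"g{i}", "c", "+", 1000 * i, 1000 * i + 10,
                                    transcripts=[make_transcript(
                                        f"t{i}", "c", "+",
                                        [(1000 * i, 1000 * i + 10)],
                                        gene_id=f"g{i}", source=src)]))
        _, counts = lk.contribution_matrix(aset)
        assert all("&" not in k for k in counts.index)

    def test_membership_counts_sum_to_total_genes(self, small_spec):
        ref, cands, _ = fx.gen_annotations(small_spec)
        merged, _ = lk.merge_all(ref, cands)
        _, counts = lk.contribution_matrix(merged)
        assert counts.sum() == len(merged)

    def test_planted_memberships_recovered(self, small_spec):
        ref, cands, truth = fx.gen_annotations(small_spec)
        merged, reports = lk.merge_all(ref, cands)
        table, _ = lk.contribution_matrix(merged)
        by_gene = table.set_index("gene_id")
        # every enclosed candidate's source must appear on its target gene
        for rep in reports:
            for gid, (fate, target) in rep.gene_fates.items():
                if fate == "merged_into":
                    src = gid.split("_")[0]
                    assert by_gene.loc[target, src]
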
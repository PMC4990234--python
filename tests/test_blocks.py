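"""Coverage-block construction: unit rules and oracle equivalence."""

import pytest

from mossdge.blocks import (
    CoverageBlock,
    annotate_overlap,
    build_coverage_blocks,
    join_by_junctions,
    merge_adjacent,
    prune_singletons,
    refine_with_gene_models,
)
from mossdge.io import AlignmentInterval, GeneModel, SpliceJunction

from conftest import alignments_to_reads, junctions_to_tuples, models_to_tuples, random_instance
from oracle_blocks import canonical_impl, oracle_coverage, oracle_pipeline, canonical_oracle


def reads(*spans, sample="control"):
    return [
        AlignmentInterval("chr1", s, e, sample, f"r{i}")
        for i, (s, e) in enumerate(spans)
    ]


def block(ivs, n_reads, chrom="chr1"):
    rds = [(ivs[0][0] + i % (ivs[0][1] - ivs[0][0]), "control") for i in range(n_reads)]
    return CoverageBlock(chrom, list(ivs), sorted(rds))


class TestBuild:
    def test_overlapping_reads_form_one_block(self):
        out = build_coverage_blocks(reads((0, 40), (30, 70), (100, 140)))
        assert [(b.intervals, b.read_count_total) for b in out] == [
            ([(0, 70)], 2),
            ([(100, 140)], 1),
        ]

    def test_single_read(self):
        out = build_coverage_blocks(reads((10, 50)))
        assert len(out) == 1 and out[0].intervals == [(10, 50)]

    def test_abutting_halfopen_reads_are_continuous(self):
        out = build_coverage_blocks(reads((0, 40), (40, 80)))
        assert [b.intervals for b in out] == [[(0, 80)]]

    def test_empty_input(self):
        assert build_coverage_blocks([]) == []

    def test_spliced_read_counted_once(self):
        aln = [
            AlignmentInterval("chr1", 0, 20, "control", "spliced"),
            AlignmentInterval("chr1", 900, 920, "control", "spliced"),
        ]
        out = build_coverage_blocks(aln)
        assert len(out) == 2
        assert sum(b.read_count_total for b in out) == 1
        assert out[0].read_count_total == 1  # anchored at leftmost segment


class TestMerge:
    def test_gap_500_merges(self):
        out = merge_adjacent([block([(0, 100)], 2), block([(600, 700)], 2)])
        assert [b.intervals for b in out] == [[(0, 700)]]

    def test_gap_501_does_not_merge(self):
        out = merge_adjacent([block([(0, 100)], 2), block([(601, 700)], 2)])
        assert len(out) == 2

    def test_chain_merges_transitively(self):
        chain = [block([(i * 500, i * 500 + 100)], 2) for i in range(4)]
        out = merge_adjacent(chain)
        assert [b.intervals for b in out] == [[(0, 1600)]]

    def test_idempotent(self):
        blocks = [block([(0, 100)], 2), block([(900, 1000)], 3)]
        once = merge_adjacent(blocks)
        assert canonical_impl(merge_adjacent(once)) == canonical_impl(once)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            merge_adjacent([block([(900, 1000)], 2), block([(0, 100)], 2)])

    def test_counts_summed(self):
        out = merge_adjacent([block([(0, 100)], 2), block([(300, 400)], 5)])
        assert out[0].read_count_total == 7


class TestPrune:
    def test_singletons_removed(self):
        blocks = [block([(i * 2000, i * 2000 + 100)], n) for i, n in enumerate([1, 2, 1, 5])]
        out = prune_singletons(blocks)
        assert [b.read_count_total for b in out] == [2, 5]

    def test_empty(self):
        assert prune_singletons([]) == []


class TestJunctionJoin:
    def test_joins_across_intron(self):
        a, b = block([(100, 200)], 2), block([(9000, 9200)], 2)
        jx = [SpliceJunction("chr1", 190, 9125)]  # span 8935 < 10000
        out = join_by_junctions([a, b], jx)
        assert len(out) == 1
        assert out[0].intervals == [(100, 200), (9000, 9200)]
        assert out[0].read_count_total == 4

    def test_span_10000_excluded(self):
        # donor anchor (199) in A, acceptor (10200) in B, but span == 10000
        # exactly: the "less than 10 kb" rule is strict, so no join.
        a, b = block([(100, 200)], 2), block([(10200, 10400)], 2)
        jx = [SpliceJunction("chr1", 200, 10200)]
        assert jx[0].span == 10_000
        assert len(join_by_junctions([a, b], jx)) == 2
        # one base shorter joins
        jx2 = [SpliceJunction("chr1", 201, 10200)]
        a2 = block([(100, 201)], 2)
        assert len(join_by_junctions([a2, b], jx2)) == 1

    def test_acceptor_outside_blocks_ignored(self):
        a = block([(100, 200)], 2)
        jx = [SpliceJunction("chr1", 190, 5000)]
        out = join_by_junctions([a], jx)
        assert canonical_impl(out) == canonical_impl([a])

    def test_transitive(self):
        blocks = [block([(i * 3000, i * 3000 + 100)], 2) for i in range(3)]
        jx = [
            SpliceJunction("chr1", 100, 3000),
            SpliceJunction("chr1", 3100, 6000),
        ]
        out = join_by_junctions(blocks, jx)
        assert len(out) == 1 and len(out[0].intervals) == 3

    def test_never_joins_across_chromosomes(self):
        a = block([(100, 200)], 2)
        b = CoverageBlock("chr2", [(100, 200)], [(100, "control"), (150, "control")])
        jx = [SpliceJunction("chr1", 190, 100)] if False else []
        out = join_by_junctions([a, b], jx)
        assert len(out) == 2


class TestRefine:
    def test_two_blocks_in_one_model_joined(self):
        blocks = [block([(1000, 1200)], 2), block([(1800, 2000)], 2)]
        models = [GeneModel("chr1", 900, 2100, "g1")]
        out = refine_with_gene_models(blocks, models)
        assert len(out) == 1 and out[0].read_count_total == 4

    def test_split_at_midpoint_between_models(self):
        b = CoverageBlock(
            "chr1", [(900, 2100)], [(i, "control") for i in range(900, 2100, 100)]
        )
        models = [GeneModel("chr1", 500, 1000, "a"), GeneModel("chr1", 2000, 2500, "b")]
        out = refine_with_gene_models([b], models)
        assert [x.intervals for x in out] == [[(900, 1500)], [(1500, 2100)]]
        assert sum(x.read_count_total for x in out) == b.read_count_total

    def test_three_models_two_split_points(self):
        b = CoverageBlock(
            "chr1", [(0, 5000)], [(i, "control") for i in range(0, 5000, 200)]
        )
        models = [
            GeneModel("chr1", 100, 1000, "a"),
            GeneModel("chr1", 2000, 2800, "b"),
            GeneModel("chr1", 4000, 4800, "c"),
        ]
        out = refine_with_gene_models([b], models)
        assert [x.intervals for x in out] == [
            [(0, 1500)],
            [(1500, 3400)],
            [(3400, 5000)],
        ]

    def test_overlapping_models_rejected(self):
        with pytest.raises(ValueError):
            refine_with_gene_models(
                [], [GeneModel("chr1", 0, 100, "a"), GeneModel("chr1", 50, 150, "b")]
            )

    def test_idempotent(self, small_sim):
        _, truth, aln = small_sim
        blocks = prune_singletons(merge_adjacent(build_coverage_blocks(aln)))
        blocks = join_by_junctions(blocks, truth.junctions)
        once = refine_with_gene_models(blocks, truth.gene_models)
        twice = refine_with_gene_models(once, truth.gene_models)
        assert canonical_impl(twice) == canonical_impl(once)


class TestAnnotate:
    def test_halfopen_abutment_is_no_overlap(self):
        b = block([(0, 100)], 2)
        annotate_overlap([b], [GeneModel("chr1", 100, 200, "g")])
        assert b.overlap_gene_ids == []

    def test_one_base_overlap_counts(self):
        b = block([(0, 100)], 2)
        annotate_overlap([b], [GeneModel("chr1", 99, 200, "g")])
        assert b.overlap_gene_ids == ["g"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        aln, _, models = random_instance(2 * seed)  # structured instances
        blocks = build_coverage_blocks(aln)
        annotate_overlap(blocks, models)
        for b in blocks:
            expected = sorted(
                m.id
                for m in models
                if m.chrom == b.chrom
                and any(s < m.end and m.start < e for s, e in b.intervals)
            )
            assert sorted(b.overlap_gene_ids) == expected


class TestPipelineProperties:
    @pytest.mark.parametrize("seed", range(12))
    def test_full_pipeline_matches_bruteforce_oracle(self, seed):
        aln, junctions, models = random_instance(seed)
        expected = oracle_pipeline(
            alignments_to_reads(aln),
            junctions_to_tuples(junctions),
            models_to_tuples(models),
        )
        blocks = build_coverage_blocks(aln)
        blocks = merge_adjacent(blocks)
        blocks = prune_singletons(blocks)
        blocks = join_by_junctions(blocks, junctions)
        blocks = refine_with_gene_models(blocks, models)
        assert canonical_impl(blocks) == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_read_count_conservation(self, seed):
        aln, junctions, models = random_instance(seed)
        n_reads = len(alignments_to_reads(aln))
        blocks = build_coverage_blocks(aln)
        assert sum(b.read_count_total for b in blocks) == n_reads
        merged = merge_adjacent(blocks)
        assert sum(b.read_count_total for b in merged) == n_reads
        pruned = prune_singletons(merged)
        n_deleted = sum(1 for b in merged if b.read_count_total == 1)
        assert sum(b.read_count_total for b in pruned) == n_reads - n_deleted
        joined = join_by_junctions(pruned, junctions)
        refined = refine_with_gene_models(joined, models)
        assert sum(b.read_count_total for b in refined) == n_reads - n_deleted

    def test_coverage_oracle_agrees_on_build(self, small_sim):
        _, _, aln = small_sim
        expected = canonical_oracle(oracle_coverage(alignments_to_reads(aln)))
        assert canonical_impl(build_coverage_blocks(aln)) == expected
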
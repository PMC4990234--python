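"""Construction of expression "coverage blocks" from uniquely mapped reads.

A coverage block is the expression unit used in place of transcript
models: a maximal stretch of continuous read coverage, post-processed by
(1) merging blocks separated by small gaps, (2) deleting single-read
blocks, (3) joining blocks connected by splice junctions, and
(4) refining against annotated gene models (join blocks inside one
model, split blocks crossing two models at the inter-model midpoint).

Blocks carry their member reads (anchored at the read's leftmost aligned
base), so per-sample counts are conserved exactly through every
transformation except the explicit single-read deletion.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from mossdge.io import AlignmentInterval, GeneModel, SpliceJunction

# A read anchor: (leftmost aligned base, sample label)
ReadAnchor = tuple[int, str]


@dataclass
class CoverageBlock:
    """One expression unit: ordered disjoint intervals plus member reads."""

    chrom: str
    intervals: list[tuple[int, int]]
    reads: list[ReadAnchor] = field(default_factory=list)
    block_id: str | None = None
    overlap_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("block must have at least one interval")
        prev_end = -1
        for s, e in self.intervals:
            if s >= e:
                raise ValueError(f"empty interval [{s},{e})")
            if s < prev_end:
                raise ValueError("block intervals must be sorted and disjoint")
            prev_end = e

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Convex hull of the intervals (used for gene-model tests)."""
        return (self.start, self.end)

    @property
    def read_count_total(self) -> int:
        return len(self.reads)

    @property
    def sample_counts(self) -> dict[str, int]:
        return dict(Counter(s for _, s in self.reads))

    def contains(self, pos: int) -> bool:
        """Whether ``pos`` falls inside one of the block's intervals."""
        i = bisect_right([s for s, _ in self.intervals], pos) - 1
        return i >= 0 and pos < self.intervals[i][1]


def _union_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge overlapping or abutting intervals into a disjoint sorted list."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _sort_blocks(blocks: list[CoverageBlock]) -> list[CoverageBlock]:
    return sorted(blocks, key=lambda b: (b.chrom, b.start, b.end))


def _check_sorted_disjoint(blocks: Sequence[CoverageBlock]) -> None:
    last: dict[str, int] = {}
    for b in blocks:
        if b.start < last.get(b.chrom, -1):
            raise ValueError("blocks must be sorted and disjoint per chromosome")
        last[b.chrom] = b.end


def build_coverage_blocks(
    alignments: Sequence[AlignmentInterval],
) -> list[CoverageBlock]:
    """Identify maximal stretches of continuous read coverage.

    Each block is the union of overlapping (or exactly abutting,
    half-open) read segments. A read is attached to the block containing
    its leftmost aligned base; spliced reads (several segments sharing a
    read id) are attached once.
    """
    if not alignments:
        return []
    # Group segments into reads; anonymous segments are their own read.
    reads: dict[object, list[AlignmentInterval]] = {}
    for i, seg in enumerate(alignments):
        key = (seg.sample, seg.read_id) if seg.read_id is not None else ("", i)
        reads.setdefault(key, []).append(seg)

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    anchors: dict[str, list[ReadAnchor]] = {}
    for segs in reads.values():
        chroms = {s.chrom for s in segs}
        if len(chroms) > 1:
            raise ValueError("segments of one read must share a chromosome")
        chrom = segs[0].chrom
        for s in segs:
            by_chrom.setdefault(chrom, []).append((s.start, s.end))
        anchors.setdefault(chrom, []).append(
            (min(s.start for s in segs), segs[0].sample)
        )

    out: list[CoverageBlock] = []
    for chrom in sorted(by_chrom):
        ivs = _union_intervals(by_chrom[chrom])
        starts = [s for s, _ in ivs]
        members: list[list[ReadAnchor]] = [[] for _ in ivs]
        for anchor in anchors[chrom]:
            i = bisect_right(starts, anchor[0]) - 1
            members[i].append(anchor)
        for (s, e), m in zip(ivs, members):
            out.append(CoverageBlock(chrom, [(s, e)], sorted(m)))
    return out


def merge_adjacent(
    blocks: Sequence[CoverageBlock], max_gap: int = 500
) -> list[CoverageBlock]:
    """Merge consecutive same-chromosome blocks separated by <= max_gap bases.

    Merging is transitive and the merged block is the single interval
    spanning both inputs (the gap is retained inside the span). Intended
    for the stage before junction joining, where blocks are single
    intervals; multi-interval inputs are collapsed to their hull.
    """
    _check_sorted_disjoint(blocks)
    out: list[CoverageBlock] = []
    for b in blocks:
        if (
            out
            and out[-1].chrom == b.chrom
            and b.start - out[-1].end <= max_gap
        ):
            prev = out[-1]
            out[-1] = CoverageBlock(
                b.chrom,
                [(prev.start, max(prev.end, b.end))],
                sorted(prev.reads + b.reads),
            )
        else:
            out.append(
                CoverageBlock(b.chrom, [b.span], sorted(b.reads))
            )
    return out


def prune_singletons(blocks: Iterable[CoverageBlock]) -> list[CoverageBlock]:
    """Delete blocks containing exactly one read (applied after merging)."""
    return [b for b in blocks if b.read_count_total != 1]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _fuse(blocks: list[CoverageBlock], uf: _UnionFind) -> list[CoverageBlock]:
    groups: dict[int, list[CoverageBlock]] = {}
    for i, b in enumerate(blocks):
        groups.setdefault(uf.find(i), []).append(b)
    fused = []
    for members in groups.values():
        if len(members) == 1:
            fused.append(members[0])
            continue
        ivs = _union_intervals(iv for b in members for iv in b.intervals)
        reads = sorted(r for b in members for r in b.reads)
        fused.append(CoverageBlock(members[0].chrom, ivs, reads))
    return _sort_blocks(fused)


def join_by_junctions(
    blocks: Sequence[CoverageBlock],
    junctions: Iterable[SpliceJunction],
    max_span: int = 10_000,
) -> list[CoverageBlock]:
    """Join blocks connected by a splice junction with intron span < max_span.

    The junction's exonic anchors (the base before the donor and the base
    at the acceptor) are located in the blocks' intervals; when the two
    anchors fall in two distinct same-chromosome blocks, those blocks are
    joined into one multi-interval block. Joining is transitive;
    junctions with either anchor outside all blocks are ignored.
    """
    blocks = _sort_blocks(list(blocks))
    uf = _UnionFind(len(blocks))
    index: dict[str, list[int]] = {}
    for i, b in enumerate(blocks):
        index.setdefault(b.chrom, []).append(i)

    def locate(chrom: str, pos: int) -> int | None:
        idxs = index.get(chrom, [])
        starts = [blocks[i].start for i in idxs]
        k = bisect_right(starts, pos) - 1
        if k < 0:
            return None
        i = idxs[k]
        return i if blocks[i].contains(pos) else None

    for j in junctions:
        if j.span >= max_span:
            continue
        a = locate(j.chrom, j.donor - 1)  # last exonic base upstream
        b = locate(j.chrom, j.acceptor)  # first exonic base downstream
        if a is None or b is None or a == b:
            continue
        uf.union(a, b)
    return _fuse(list(blocks), uf)


def _check_models_disjoint(models: Sequence[GeneModel]) -> list[GeneModel]:
    ms = sorted(models, key=lambda m: (m.chrom, m.start))
    for a, b in zip(ms, ms[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"gene models {a.id} and {b.id} overlap")
    return ms


def _hull_overlaps(b: CoverageBlock, m: GeneModel) -> bool:
    s, e = b.span
    return b.chrom == m.chrom and s < m.end and m.start < e


def _split_block(
    block: CoverageBlock, points: Sequence[int]
) -> list[CoverageBlock]:
    """Split a block at the given positions (strictly inside its span).

    Intervals straddling a split point are cut; reads go to the part
    containing their leftmost base. Parts left without intervals are
    dropped (possible when a split point falls in an internal gap whose
    side holds no coverage)."""
    bounds = [block.start] + sorted(points) + [block.end]
    parts_iv: list[list[tuple[int, int]]] = [[] for _ in range(len(bounds) - 1)]
    parts_rd: list[list[ReadAnchor]] = [[] for _ in range(len(bounds) - 1)]
    for s, e in block.intervals:
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            cs, ce = max(s, lo), min(e, hi)
            if cs < ce:
                parts_iv[k].append((cs, ce))
    for r in block.reads:
        k = bisect_right(bounds, r[0], 1, len(bounds) - 1) - 1
        parts_rd[k].append(r)
    out = []
    for ivs, rds in zip(parts_iv, parts_rd):
        if ivs:
            out.append(CoverageBlock(block.chrom, ivs, sorted(rds)))
    return out


def refine_with_gene_models(
    blocks: Sequence[CoverageBlock], models: Sequence[GeneModel]
) -> list[CoverageBlock]:
    """Refine blocks against non-overlapping gene models, to fixpoint.

    (i) blocks whose spans intersect the same model are joined;
    (ii) a block whose span crosses two or more models is split at
    floor((upstream model end + downstream model start) / 2) for each
    consecutive crossed pair.
    """
    ms = _check_models_disjoint(models)
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in ms:
        by_chrom.setdefault(m.chrom, []).append(m)

    current = _sort_blocks(list(blocks))
    while True:
        # (i) join blocks sharing a model, transitively, to fixpoint
        uf = _UnionFind(len(current))
        model_members: dict[tuple[str, str], list[int]] = {}
        for i, b in enumerate(current):
            for m in by_chrom.get(b.chrom, []):
                if _hull_overlaps(b, m):
                    model_members.setdefault((m.chrom, m.id), []).append(i)
        for members in model_members.values():
            for i, j in zip(members, members[1:]):
                uf.union(i, j)
        current = _fuse(current, uf)

        # (ii) split blocks crossing >=2 models
        split_any = False
        next_blocks: list[CoverageBlock] = []
        for b in current:
            crossed = [m for m in by_chrom.get(b.chrom, []) if _hull_overlaps(b, m)]
            if len(crossed) < 2:
                next_blocks.append(b)
                continue
            points = [
                (a.end + c.start) // 2 for a, c in zip(crossed, crossed[1:])
            ]
            parts = _split_block(b, points)
            split_any = split_any or len(parts) > 1
            next_blocks.extend(parts)
        current = _sort_blocks(next_blocks)
        if not split_any:
            return current


def annotate_overlap(
    blocks: Sequence[CoverageBlock], models: Sequence[GeneModel]
) -> list[CoverageBlock]:
    """Record, per block, the gene models any block interval intersects
    by at least one base (half-open overlap)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in sorted(models, key=lambda m: (m.chrom, m.start)):
        by_chrom.setdefault(m.chrom, []).append(m)
    for b in blocks:
        ids = []
        for m in by_chrom.get(b.chrom, []):
            if m.start >= b.end:
                break
            if any(s < m.end and m.start < e for s, e in b.intervals):
                ids.append(m.id)
        b.overlap_gene_ids = ids
    return list(blocks)


def assign_block_ids(blocks: Sequence[CoverageBlock]) -> list[CoverageBlock]:
    """Give blocks stable positional identifiers (BLK00001, ...)."""
    for i, b in enumerate(_sort_blocks(list(blocks))):
        b.block_id = f"BLK{i + 1:05d}"
    return _sort_blocks(list(blocks))


def write_blocks_bed(blocks: Sequence[CoverageBlock], path: str) -> None:
    """One BED line per block interval, block id in the name column."""
    with open(path, "w") as fh:
        for b in blocks:
            for s, e in b.intervals:
                fh.write(f"{b.chrom}\t{s}\t{e}\t{b.block_id or '.'}\n")


def write_blocks_tsv(
    blocks: Sequence[CoverageBlock], path: str, samples: Sequence[str]
) -> None:
    with open(path, "w") as fh:
        cols = ["block_id", "chrom", "start", "end", "n_intervals"]
        cols += [f"count_{s}" for s in samples]
        cols += ["overlap_gene_ids"]
        fh.write("\t".join(cols) + "\n")
        for b in blocks:
            counts = b.sample_counts
            row = [
                b.block_id or ".",
                b.chrom,
                str(b.start),
                str(b.end),
                str(len(b.intervals)),
            ]
            row += [str(counts.get(s, 0)) for s in samples]
            row += [",".join(b.overlap_gene_ids)]
            fh.write("\t".join(row) + "\n")
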
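"""Brute-force reference implementation of the block pipeline.

Deliberately naive: per-base coverage arrays and exhaustive,
one-action-at-a-time rule application. Used only as a test oracle.
Reads are (chrom, [(start, end), ...], sample) tuples.
"""

from __future__ import annotations


class OBlock:
    def __init__(self, chrom, intervals, reads):
        self.chrom = chrom
        self.intervals = sorted(intervals)
        self.reads = sorted(reads)

    @property
    def hull(self):
        return (self.intervals[0][0], self.intervals[-1][1])


def _coalesce(intervals):
    ivs = sorted(intervals)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = [out[-1][0], max(out[-1][1], e)]
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _sortkey(b):
    return (b.chrom, b.intervals[0][0])


def oracle_coverage(reads):
    """Per-base coverage array -> maximal covered runs, reads assigned
    to the run containing their leftmost base."""
    chroms = sorted({r[0] for r in reads})
    blocks = []
    for chrom in chroms:
        rs = [r for r in reads if r[0] == chrom]
        length = max(e for r in rs for _, e in r[1]) + 1
        cov = [False] * length
        for _, segs, _ in rs:
            for s, e in segs:
                for i in range(s, e):
                    cov[i] = True
        runs = []
        i = 0
        while i < length:
            if cov[i]:
                j = i
                while j < length and cov[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        for s, e in runs:
            members = []
            for _, segs, sample in rs:
                anchor = min(x for x, _ in segs)
                if s <= anchor < e:
                    members.append((anchor, sample))
            blocks.append(OBlock(chrom, [(s, e)], members))
    return sorted(blocks, key=_sortkey)


def oracle_merge(blocks, max_gap=500):
    """Repeated pairwise merging to fixpoint; merged block is the hull."""
    blocks = sorted(blocks, key=_sortkey)
    changed = True
    while changed:
        changed = False
        for i in range(len(blocks) - 1):
            a, b = blocks[i], blocks[i + 1]
            if a.chrom == b.chrom and b.hull[0] - a.hull[1] <= max_gap:
                merged = OBlock(
                    a.chrom,
                    [(a.hull[0], max(a.hull[1], b.hull[1]))],
                    a.reads + b.reads,
                )
                blocks = blocks[:i] + [merged] + blocks[i + 2 :]
                changed = True
                break
    # pre-junction stage: collapse any multi-interval leftovers to hulls
    return sorted(
        [OBlock(b.chrom, [b.hull], b.reads) for b in blocks], key=_sortkey
    )


def oracle_prune(blocks):
    return [b for b in blocks if len(b.reads) != 1]


def _find_block(blocks, chrom, pos):
    for i, b in enumerate(blocks):
        if b.chrom != chrom:
            continue
        for s, e in b.intervals:
            if s <= pos < e:
                return i
    return None


def oracle_junction_join(blocks, junctions, max_span=10_000):
    blocks = sorted(blocks, key=_sortkey)
    changed = True
    while changed:
        changed = False
        for chrom, donor, acceptor in junctions:
            if acceptor - donor >= max_span:
                continue
            i = _find_block(blocks, chrom, donor - 1)
            j = _find_block(blocks, chrom, acceptor)
            if i is None or j is None or i == j:
                continue
            a, b = blocks[i], blocks[j]
            merged = OBlock(
                chrom, _coalesce(a.intervals + b.intervals), a.reads + b.reads
            )
            blocks = [x for k, x in enumerate(blocks) if k not in (i, j)]
            blocks.append(merged)
            blocks = sorted(blocks, key=_sortkey)
            changed = True
            break
    return blocks


def _crossed(b, models):
    out = []
    for chrom, ms, me, mid in sorted(models, key=lambda m: (m[0], m[1])):
        if chrom == b.chrom and b.hull[0] < me and ms < b.hull[1]:
            out.append((chrom, ms, me, mid))
    return out


def oracle_refine(blocks, models):
    blocks = sorted(blocks, key=_sortkey)
    while True:
        # join rule first, one action at a time
        acted = False
        for m in models:
            hits = [i for i, b in enumerate(blocks) if _crossed(b, [m])]
            if len(hits) >= 2:
                i, j = hits[0], hits[1]
                a, b = blocks[i], blocks[j]
                merged = OBlock(
                    a.chrom, _coalesce(a.intervals + b.intervals), a.reads + b.reads
                )
                blocks = [x for k, x in enumerate(blocks) if k not in (i, j)]
                blocks.append(merged)
                blocks = sorted(blocks, key=_sortkey)
                acted = True
                break
        if acted:
            continue
        # then split rule
        for i, b in enumerate(blocks):
            crossed = _crossed(b, models)
            if len(crossed) < 2:
                continue
            points = [
                (crossed[k][2] + crossed[k + 1][1]) // 2
                for k in range(len(crossed) - 1)
            ]
            bounds = [b.hull[0]] + points + [b.hull[1]]
            parts = []
            for k in range(len(bounds) - 1):
                lo, hi = bounds[k], bounds[k + 1]
                ivs = []
                for s, e in b.intervals:
                    cs, ce = max(s, lo), min(e, hi)
                    if cs < ce:
                        ivs.append((cs, ce))
                rds = [r for r in b.reads if lo <= r[0] < hi]
                if ivs:
                    parts.append(OBlock(b.chrom, ivs, rds))
            if len(parts) > 1 or (parts and parts[0].intervals != b.intervals):
                blocks = blocks[:i] + blocks[i + 1 :] + parts
                blocks = sorted(blocks, key=_sortkey)
                acted = True
                break
        if not acted:
            return blocks


def oracle_pipeline(reads, junctions, models, max_gap=500, max_span=10_000):
    blocks = oracle_coverage(reads)
    blocks = oracle_merge(blocks, max_gap)
    blocks = oracle_prune(blocks)
    blocks = oracle_junction_join(blocks, junctions, max_span)
    blocks = oracle_refine(blocks, models)
    return canonical_oracle(blocks)


def canonical_oracle(blocks):
    return sorted(
        (b.chrom, tuple(b.intervals), tuple(sorted(b.reads))) for b in blocks
    )


def canonical_impl(blocks):
    return sorted(
        (b.chrom, tuple(b.intervals), tuple(sorted(b.reads))) for b in blocks
    )
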
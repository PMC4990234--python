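"""Digital differential expression for block counts.

The significance test is the Audic-Claverie statistic for comparing two
tag counts under Poisson sampling: given x reads in a library of N1 and
y reads in a library of N2, the posterior predictive distribution of y
given x (flat prior on the Poisson rate) is

    P(Y = y | x) = r^y * (x + y)! / (x! * y! * (1 + r)^(x + y + 1)),
    r = N2 / N1,

which is the negative binomial NB(x + 1, N1 / (N1 + N2)). Tail
probabilities are evaluated through the regularized incomplete beta
function (log-gamma based), so they stay finite for counts up to and
beyond 1e6. The two-sided p-value doubles the smaller tail, capped at
1; because the conditional tails are not exactly exchangeable in the
discrete boundary term, the statistic is evaluated in both orientations
(y given x, and x given y with the library sizes swapped) and the
smaller doubled tail is taken, which makes the p-value exactly
symmetric under (x, N1) <-> (y, N2).

Expression per block is reported as reads per million uniquely mapped
reads (RPM); the differential-expression report applies the fold-change
and minimum-read filters used to define the up/down-regulated lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

from mossdge.blocks import CoverageBlock
from mossdge.io import AlignmentInterval


@dataclass(frozen=True)
class BlockCounts:
    """Per-block read counts in the two conditions with library sizes."""

    block_id: str
    x: int  # condition 1 (control)
    y: int  # condition 2 (treated)
    N1: int
    N2: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError("library sizes must be >= 1")


@dataclass
class DEResult:
    block_id: str
    x: int
    y: int
    rpm1: float
    rpm2: float
    fold: float
    log2_fc: float
    p: float
    q: float = math.nan
    direction: str = "none"  # up | down | none
    passes_filters: bool = False


def count_reads_per_block(
    blocks: Sequence[CoverageBlock],
    alignments: Sequence[AlignmentInterval],
    sample1: str,
    sample2: str,
    N1: int,
    N2: int,
) -> list[BlockCounts]:
    """Assign each read to the block whose intervals contain its leftmost
    aligned base; reads starting in no block are unassigned.

    Spliced reads (several segments sharing a read id) are counted once,
    at the leftmost segment.
    """
    from bisect import bisect_right

    anchors: dict[object, tuple[str, int, str]] = {}
    for i, seg in enumerate(alignments):
        key = (seg.sample, seg.read_id) if seg.read_id is not None else ("", i)
        prev = anchors.get(key)
        if prev is None or seg.start < prev[1]:
            anchors[key] = (seg.chrom, seg.start, seg.sample)

    by_chrom: dict[str, list[int]] = {}
    ordered = sorted(range(len(blocks)), key=lambda i: (blocks[i].chrom, blocks[i].start))
    for i in ordered:
        by_chrom.setdefault(blocks[i].chrom, []).append(i)

    counts = [{sample1: 0, sample2: 0} for _ in blocks]
    for chrom, pos, sample in anchors.values():
        idxs = by_chrom.get(chrom)
        if not idxs:
            continue
        starts = [blocks[i].start for i in idxs]
        k = bisect_right(starts, pos) - 1
        if k < 0:
            continue
        i = idxs[k]
        if blocks[i].contains(pos) and sample in counts[i]:
            counts[i][sample] += 1

    out = []
    for i, b in enumerate(blocks):
        out.append(
            BlockCounts(
                block_id=b.block_id or f"BLK{i + 1:05d}",
                x=counts[i][sample1],
                y=counts[i][sample2],
                N1=N1,
                N2=N2,
            )
        )
    return out


def rpm_and_log_fc(
    counts: BlockCounts, pseudocount: float = 0.5
) -> tuple[float, float, float]:
    """RPM in each condition and the log2 fold change (treated/control).

    When either count is zero, half a read (in RPM units, per library)
    is added to both conditions so the ratio stays finite and the
    fold-change filter remains evaluable; with both counts positive the
    plain RPM ratio is used.
    """
    rpm1 = counts.x * 1e6 / counts.N1
    rpm2 = counts.y * 1e6 / counts.N2
    if counts.x > 0 and counts.y > 0:
        log2_fc = math.log2(rpm2 / rpm1)
    else:
        c1 = pseudocount * 1e6 / counts.N1
        c2 = pseudocount * 1e6 / counts.N2
        log2_fc = math.log2((rpm2 + c2) / (rpm1 + c1))
    return rpm1, rpm2, log2_fc


def audic_claverie_pmf(y, x, N1, N2):
    """P(Y = y | x) in log-gamma space; vectorized."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    r = float(N2) / float(N1)
    logp = (
        y * math.log(r)
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * math.log1p(r)
    )
    return np.exp(logp)


def _tail_min(x, y, p1, p2):
    """min(P(Y <= y | x), P(Y >= y | x)) for Y ~ NB(x + 1, p1), p2 = 1 - p1.

    p1 and p2 are passed separately (each computed directly from the
    library sizes) so that swapping (x, N1) <-> (y, N2) evaluates
    bit-identical expressions.
    """
    lower = betainc(x + 1.0, y + 1.0, p1)  # P(Y <= y | x)
    upper = np.where(y > 0, betainc(np.maximum(y, 1.0), x + 1.0, p2), 1.0)
    return np.minimum(lower, upper)


def audic_claverie_p(x, y, N1, N2):
    """Two-sided Audic-Claverie p-value; scalar or vectorized.

    p = min(1, 2 * min over both orientations of the smaller conditional
    tail), where the conditional law of y given x is
    NB(x + 1, N1/(N1+N2)) and the reverse orientation conditions on y
    with the library sizes swapped. Tails are regularized incomplete
    beta functions; the result is exactly symmetric under
    (x, N1) <-> (y, N2).
    """
    scalar = np.isscalar(x) and np.isscalar(y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(x != np.floor(x)) or np.any(y != np.floor(y)):
        raise ValueError("counts must be integers")
    if N1 < 1 or N2 < 1:
        raise ValueError("library sizes must be >= 1")
    total = float(N1) + float(N2)
    p1 = float(N1) / total
    p2 = float(N2) / total
    tails = np.minimum(_tail_min(x, y, p1, p2), _tail_min(y, x, p2, p1))
    p = np.minimum(1.0, 2.0 * tails)
    return float(p) if scalar else p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_differential_expression(
    counts: Sequence[BlockCounts], pseudocount: float = 0.5
) -> list[DEResult]:
    """RPM, log fold change, Audic-Claverie p and BH q for each block."""
    if not counts:
        return []
    x = np.array([c.x for c in counts])
    y = np.array([c.y for c in counts])
    N1, N2 = counts[0].N1, counts[0].N2
    pvals = audic_claverie_p(x, y, N1, N2)
    qvals = bh_adjust(pvals)
    out = []
    for c, p, q in zip(counts, pvals, qvals):
        rpm1, rpm2, lfc = rpm_and_log_fc(c, pseudocount)
        out.append(
            DEResult(
                block_id=c.block_id,
                x=c.x,
                y=c.y,
                rpm1=rpm1,
                rpm2=rpm2,
                fold=2.0 ** abs(lfc),
                log2_fc=lfc,
                p=float(p),
                q=float(q),
            )
        )
    return out


def classify_de(
    results: Iterable[DEResult],
    min_fold: float = 3.0,
    min_reads: int = 50,
    q_threshold: float | None = None,
) -> list[DEResult]:
    """Apply the fold-change and minimum-read filters and set direction.

    A block passes when the RPM ratio is >= min_fold in either
    direction, max(x, y) >= min_reads, and (when a q threshold is given)
    q <= q_threshold. Direction follows the sign of the log fold change.
    """
    out = []
    for r in results:
        passes = (
            max(r.x, r.y) >= min_reads
            and r.fold >= min_fold
            and (q_threshold is None or r.q <= q_threshold)
        )
        r.passes_filters = bool(passes)
        if passes and r.log2_fc > 0:
            r.direction = "up"
        elif passes and r.log2_fc < 0:
            r.direction = "down"
        else:
            r.direction = "none"
            r.passes_filters = False if r.log2_fc == 0 else r.passes_filters
        out.append(r)
    return out
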
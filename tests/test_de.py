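"""Digital-expression statistics: RPM, the Audic-Claverie test, BH, filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import nbinom

from mossdge.blocks import build_coverage_blocks, merge_adjacent
from mossdge.de import (
    BlockCounts,
    audic_claverie_p,
    audic_claverie_pmf,
    bh_adjust,
    classify_de,
    count_reads_per_block,
    rpm_and_log_fc,
    compute_differential_expression,
)
from mossdge.io import AlignmentInterval


def _tail_by_summation(x, y, N1, N2, kmax=20_000):
    """min conditional tail of y given x, by direct summation of the
    mass function (log-gamma per term, no incomplete-beta shortcut)."""
    r = N2 / N1

    def pmf(k):
        return math.exp(
            k * math.log(r)
            + gammaln(x + k + 1)
            - gammaln(x + 1)
            - gammaln(k + 1)
            - (x + k + 1) * math.log1p(r)
        )

    lower = sum(pmf(k) for k in range(0, y + 1))
    upper = sum(pmf(k) for k in range(y, kmax))
    return min(lower, upper)


def ac_p_by_summation(x, y, N1, N2):
    """Independent oracle for the symmetrized two-sided p-value."""
    return min(
        1.0,
        2.0
        * min(
            _tail_by_summation(x, y, N1, N2), _tail_by_summation(y, x, N2, N1)
        ),
    )


class TestAudicClaverie:
    def test_no_counts_no_signal(self):
        assert audic_claverie_p(0, 0, 10**6, 10**6) == 1.0

    def test_ten_vs_zero_equal_libraries(self):
        # P(Y=0 | x=10) = 1/2^11 = 1/2048; doubled lower tail
        assert audic_claverie_p(10, 0, 10**6, 10**6) == pytest.approx(
            2 / 2048, rel=1e-12
        )

    @pytest.mark.parametrize(
        "x,y,N1,N2",
        [
            (5, 15, 10**6, 10**6),
            (5, 15, 10**6, 2 * 10**6),
            (0, 7, 10**6, 10**6),
            (12, 12, 3 * 10**6, 10**6),
            (30, 0, 10**6, 10**6),
        ],
    )
    def test_matches_direct_summation(self, x, y, N1, N2):
        expected = ac_p_by_summation(x, y, N1, N2)
        assert audic_claverie_p(x, y, N1, N2) == pytest.approx(expected, rel=1e-10)

    def test_matches_negative_binomial_cross_check(self):
        # The conditional law of y given x is NB(x+1, N1/(N1+N2));
        # an independent route through scipy.stats.nbinom must agree.
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = int(rng.integers(0, 500))
            y = int(rng.integers(0, 500))
            N1 = int(rng.integers(10**5, 10**7))
            N2 = int(rng.integers(10**5, 10**7))
            p1 = N1 / (N1 + N2)

            def tails(a, b, pa):
                lower = nbinom.cdf(b, a + 1, pa)
                upper = 1.0 - (nbinom.cdf(b - 1, a + 1, pa) if b > 0 else 0.0)
                return min(lower, upper)

            expected = min(
                1.0, 2.0 * min(tails(x, y, p1), tails(y, x, 1 - p1))
            )
            assert audic_claverie_p(x, y, N1, N2) == pytest.approx(expected, rel=1e-9)

    def test_pmf_normalizes(self):
        for x, r in [(0, 1.0), (5, 1.0), (50, 0.5), (200, 2.0)]:
            N1, N2 = 10**6, int(r * 10**6)
            total = audic_claverie_pmf(np.arange(0, 50_000), x, N1, N2).sum()
            assert abs(total - 1.0) < 1e-12

    @given(
        x=st.integers(0, 300),
        y=st.integers(0, 300),
        N1=st.integers(10**4, 10**7),
        N2=st.integers(10**4, 10**7),
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetry(self, x, y, N1, N2):
        assert audic_claverie_p(x, y, N1, N2) == pytest.approx(
            audic_claverie_p(y, x, N2, N1), rel=1e-9, abs=1e-300
        )

    def test_finite_at_million_counts(self):
        p = audic_claverie_p(1_000_000, 1_002_000, 10**7, 10**7)
        assert 0.0 < p <= 1.0 and math.isfinite(p)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            audic_claverie_p(-1, 3, 10, 10)


class TestRpmAndFold:
    def test_rpm_scale(self):
        c = BlockCounts("b", 100, 0, 10**7, 10**7)
        rpm1, _, _ = rpm_and_log_fc(c)
        assert rpm1 == 10.0

    def test_symmetric_counts_zero_lfc(self):
        _, _, lfc = rpm_and_log_fc(BlockCounts("b", 55, 55, 10**6, 10**6))
        assert lfc == 0.0

    def test_sixfold(self):
        _, _, lfc = rpm_and_log_fc(BlockCounts("b", 10, 60, 10**6, 10**6))
        assert lfc == pytest.approx(math.log2(6.0), abs=1e-12)

    def test_zero_count_stays_finite(self):
        _, _, lfc = rpm_and_log_fc(BlockCounts("b", 0, 40, 10**6, 10**6))
        assert math.isfinite(lfc) and lfc == pytest.approx(math.log2(40.5 / 0.5))


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_manual_stepup_and_is_monotone(self, pvals):
        q = bh_adjust(pvals)
        # independent oracle: q(i) = min_{j>=i} m*p(j)/j on the sorted p
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        manual = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, m * p[order[rank - 1]] / rank)
            manual[order[rank - 1]] = min(1.0, running)
        assert q == pytest.approx(manual, rel=1e-12, abs=1e-15)
        assert np.all(q[order][1:] - q[order][:-1] >= -1e-15)
        assert np.all(q >= p - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestClassify:
    def run_one(self, x, y, **kw):
        res = compute_differential_expression([BlockCounts("b", x, y, 10**6, 10**6)])
        return classify_de(res, **kw)[0]

    def test_sixfold_sixty_reads_passes_up(self):
        r = self.run_one(10, 60)
        assert r.passes_filters and r.direction == "up"

    def test_under_threefold_fails(self):
        r = self.run_one(10, 25)
        assert not r.passes_filters and r.direction == "none"

    def test_fourfold_but_few_reads_fails(self):
        r = self.run_one(5, 20)
        assert not r.passes_filters

    def test_down_direction(self):
        r = self.run_one(60, 10)
        assert r.passes_filters and r.direction == "down"

    def test_q_threshold_optional(self):
        r = self.run_one(10, 60, q_threshold=1e-12)
        assert not r.passes_filters


class TestCounting:
    def test_read_inside_block(self):
        aln = [AlignmentInterval("chr1", 10, 50, "control", "r1")]
        blocks = build_coverage_blocks(aln)
        counts = count_reads_per_block(blocks, aln, "control", "treated", 100, 100)
        assert counts[0].x == 1 and counts[0].y == 0

    def test_read_in_retained_merge_gap_is_counted(self):
        base = [
            AlignmentInterval("chr1", 0, 40, "control", "a"),
            AlignmentInterval("chr1", 0, 40, "control", "b"),
            AlignmentInterval("chr1", 400, 440, "control", "c"),
            AlignmentInterval("chr1", 400, 440, "control", "d"),
        ]
        blocks = merge_adjacent(build_coverage_blocks(base))
        assert len(blocks) == 1  # span [0, 440) retains the gap
        gap_read = AlignmentInterval("chr1", 100, 140, "treated", "g")
        counts = count_reads_per_block(
            blocks, base + [gap_read], "control", "treated", 100, 100
        )
        assert counts[0].x == 4 and counts[0].y == 1

    def test_read_starting_outside_unassigned(self):
        aln = [AlignmentInterval("chr1", 100, 140, "control", "r1")]
        blocks = build_coverage_blocks(aln)
        stray = AlignmentInterval("chr1", 5000, 5040, "treated", "s")
        counts = count_reads_per_block(blocks, aln + [stray], "control", "treated", 10, 10)
        assert counts[0].x == 1 and counts[0].y == 0

    @pytest.mark.parametrize("seed", [3, 9])
    def test_matches_bruteforce_assignment(self, seed):
        from conftest import alignments_to_reads, random_instance

        aln, _, _ = random_instance(seed)
        blocks = merge_adjacent(build_coverage_blocks(aln))
        counts = count_reads_per_block(blocks, aln, "control", "treated", 1000, 1000)
        reads = alignments_to_reads(aln)
        for b, c in zip(blocks, counts):
            expected = {"control": 0, "treated": 0}
            for chrom, segs, sample in reads:
                anchor = min(s for s, _ in segs)
                if chrom == b.chrom and b.contains(anchor):
                    expected[sample] += 1
            assert (c.x, c.y) == (expected["control"], expected["treated"])
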
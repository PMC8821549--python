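"""Consensus intersection vs a per-base oracle; merge and pileup behavior."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from trchip.consensus import (
    intersect_replicates,
    merge_intervals,
    peak_width_summary,
    pileup_call,
)
from trchip.io import GenomicInterval, Peak


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def pk(start, end, height=1.0, chrom="chr1"):
    return Peak(iv(start, end, chrom), height=height)


def covered_bases(intervals):
    bases = set()
    for i in intervals:
        bases.update((i.chrom, b) for b in range(i.start, i.end))
    return bases


def consensus_oracle(replicate_peaks):
    """Per-base oracle: runs of bases covered by every replicate."""
    per_rep = [
        covered_bases(p.interval for p in peaks)
        for peaks in replicate_peaks.values()
    ]
    common = set.intersection(*per_rep) if per_rep else set()
    runs = []
    for chrom in sorted({c for c, _ in common}):
        positions = sorted(b for c, b in common if c == chrom)
        start = prev = None
        for b in positions:
            if prev is None or b != prev + 1:
                if start is not None:
                    runs.append((chrom, start, prev + 1))
                start = b
            prev = b
        if start is not None:
            runs.append((chrom, start, prev + 1))
    return runs


class TestMergeIntervals:
    def test_overlap_merge(self):
        assert merge_intervals([iv(100, 200), iv(150, 250)]) == [iv(100, 250)]

    def test_bookended_intervals_merge_at_gap_zero(self):
        assert merge_intervals([iv(100, 200), iv(200, 300)]) == [iv(100, 300)]

    def test_gap_closure_threshold(self):
        pair = [iv(100, 200), iv(205, 300)]
        assert merge_intervals(pair, max_gap=4) == pair
        assert merge_intervals(pair, max_gap=5) == [iv(100, 300)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals([iv(0, 1)], max_gap=-1)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 500),
                st.integers(1, 60),
            ),
            max_size=30,
        )
    )
    def test_merge_preserves_covered_bases(self, raw):
        intervals = [iv(s, s + w, c) for c, s, w in raw]
        merged = merge_intervals(intervals)
        assert covered_bases(merged) == covered_bases(intervals)
        for a, b in zip(merged, merged[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start  # disjoint, non-adjacent


class TestIntersectReplicates:
    def test_three_replicate_example(self):
        cons = intersect_replicates(
            {
                "r1": [pk(100, 200, 5.0)],
                "r2": [pk(150, 250, 7.0)],
                "r3": [pk(180, 220, 3.0)],
            }
        )
        assert len(cons) == 1
        c = cons[0]
        assert (c.interval.start, c.interval.end) == (180, 200)
        assert c.height == 3.0  # min over replicates of max contributing
        assert set(c.support) == {"r1", "r2", "r3"}

    def test_single_replicate_is_merged_input(self):
        cons = intersect_replicates({"r1": [pk(10, 30), pk(20, 50), pk(90, 95)]})
        assert [(c.interval.start, c.interval.end) for c in cons] == [
            (10, 50),
            (90, 95),
        ]

    def test_empty_replicate_absorbs(self):
        cons = intersect_replicates(
            {"r1": [pk(0, 100)], "r2": [pk(0, 100)], "r3": []}
        )
        assert cons == []

    def test_no_replicates_rejected(self):
        with pytest.raises(ValueError):
            intersect_replicates({})

    @given(
        st.integers(1, 3),
        st.lists(
            st.tuples(
                st.integers(0, 2),  # replicate index
                st.sampled_from(["chr1", "chr2", "chr3"]),
                st.integers(0, 9999),
                st.integers(1, 400),
            ),
            max_size=50,
        ),
    )
    def test_matches_per_base_oracle(self, n_reps, raw):
        reps = {f"r{i}": [] for i in range(n_reps)}
        for rep_idx, chrom, start, width in raw:
            reps[f"r{rep_idx % n_reps}"].append(pk(start, start + width, chrom=chrom))
        cons = intersect_replicates(reps)
        got = [(c.interval.chrom, c.interval.start, c.interval.end) for c in cons]
        assert got == consensus_oracle(reps)

    @given(
        st.lists(
            st.tuples(st.integers(0, 2), st.integers(0, 3000), st.integers(1, 200)),
            min_size=3,
            max_size=30,
        ),
        st.tuples(st.integers(0, 3000), st.integers(1, 200)),
    )
    def test_adding_a_peak_never_shrinks_consensus(self, raw, extra):
        reps = {"r0": [], "r1": [], "r2": []}
        for rep_idx, start, width in raw:
            reps[f"r{rep_idx}"].append(pk(start, start + width))
        before = covered_bases(
            c.interval for c in intersect_replicates(reps)
        )
        reps["r1"].append(pk(extra[0], extra[0] + extra[1]))
        after = covered_bases(c.interval for c in intersect_replicates(reps))
        assert before <= after

    def test_removing_a_replicate_never_shrinks_consensus(self):
        reps = {
            "r1": [pk(0, 100), pk(300, 400)],
            "r2": [pk(50, 150)],
            "r3": [pk(80, 120), pk(310, 350)],
        }
        full = covered_bases(c.interval for c in intersect_replicates(reps))
        for drop in reps:
            subset = {k: v for k, v in reps.items() if k != drop}
            kept = covered_bases(
                c.interval for c in intersect_replicates(subset)
            )
            assert full <= kept

    def test_consensus_within_each_replicate_coverage(self):
        reps = {
            "r1": [pk(0, 120), pk(200, 340)],
            "r2": [pk(30, 260)],
            "r3": [pk(50, 400)],
        }
        cons_bases = covered_bases(
            c.interval for c in intersect_replicates(reps)
        )
        for peaks in reps.values():
            assert cons_bases <= covered_bases(p.interval for p in peaks)


class TestPeakWidthSummary:
    def test_fraction_below_500_strict(self):
        peaks = [pk(0, 100), pk(0, 300), pk(0, 600)]
        summary = peak_width_summary(peaks, bins=[0, 500, 1000])
        assert summary["fraction_below_500"] == pytest.approx(2 / 3)
        assert sum(summary["counts"]) == 3
        all_499 = [pk(0, 499)] * 4
        assert peak_width_summary(all_499)["fraction_below_500"] == 1.0
        assert peak_width_summary([pk(0, 500)])["fraction_below_500"] == 0.0

    def test_empty_and_unsorted_bins_rejected(self):
        with pytest.raises(ValueError):
            peak_width_summary([])
        with pytest.raises(ValueError):
            peak_width_summary([pk(0, 10)], bins=[100, 50])


class TestPileupCall:
    def test_no_fragments_no_peaks(self):
        assert pileup_call([], {"chr1": 1000}, background_rate=0.01) == []

    def test_uniform_background_coverage_no_peaks(self):
        frags = [iv(i * 100, (i + 1) * 100) for i in range(1000)] * 2
        assert pileup_call(frags, {"chr1": 100_000}, background_rate=0.02) == []

    def test_stacked_locus_poisson_oracle(self):
        """60 stacked fragments on a 100 kb chromosome, background 0.001.

        The per-base Poisson oracle: mean = 0.001 × 100 = 0.1, so coverage
        60 has survival probability astronomically below any cutoff while
        coverage 0 elsewhere has p = 1; exactly one peak must remain.
        """
        frags = [iv(5000, 5100)] * 60
        lam = 0.001 * 100
        assert stats.poisson.sf(59, lam) < 1e-50
        peaks = pileup_call(frags, {"chr1": 100_000}, background_rate=0.001)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.interval.start <= 5000 and p.interval.end >= 5100
        assert p.height == 60.0
        assert p.interval.start + p.summit_offset == 5000  # leftmost max base

    def test_q_cutoff_zero_returns_nothing(self):
        frags = [iv(5000, 5100)] * 60
        assert (
            pileup_call(frags, {"chr1": 100_000}, 0.001, q_cutoff=0.0) == []
        )

    def test_vanishing_background_returns_covered_runs(self):
        frags = [iv(100, 260)]
        peaks = pileup_call(
            frags, {"chr1": 1000}, background_rate=1e-12, min_width=1, max_gap=0
        )
        assert [(p.interval.start, p.interval.end) for p in peaks] == [(100, 260)]

    def test_zero_length_genome_rejected(self):
        with pytest.raises(ValueError):
            pileup_call([iv(0, 10)], {"chr1": 0}, background_rate=0.1)
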
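"""Replicate-consensus peak determination and a simplified pileup caller.

A *consensus peak* formalizes "a binding site seen at the same location in
every replicate": a maximal genomic run where, at every base, each replicate
of the sample has at least one called peak covering that base.  The
consensus interval is the mutually covered region (symmetric in the
replicates), its height the most conservative support measure — the minimum
over replicates of that replicate's best contributing peak height.

The pileup caller is a deliberately simple stand-in for a full ChIP-Seq
peak caller: per-base fragment coverage is tested against a Poisson
background (mean = background rate × mean fragment length), Benjamini–
Hochberg adjusted, and significant bases are merged into peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .io import GenomicInterval, Peak

__all__ = [
    "ConsensusPeak",
    "merge_intervals",
    "intersect_replicates",
    "peak_width_summary",
    "pileup_call",
]


@dataclass(frozen=True)
class ConsensusPeak:
    """A region covered by at least one peak of every replicate."""

    peak_id: str
    interval: GenomicInterval
    support: Mapping[str, tuple]  # replicate_id -> contributing Peaks
    height: float
    sample_id: Optional[str] = None

    @property
    def width(self) -> int:
        return self.interval.width


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge overlapping intervals, closing gaps of up to ``max_gap`` bases.

    Under half-open semantics, book-ended intervals ``[a, b)`` and ``[b, c)``
    merge already at ``max_gap = 0``.  Output is sorted and pairwise
    non-overlapping; with ``max_gap = 0`` total covered bases are unchanged.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be non-negative, got {max_gap}")
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur = ordered[0]
    for iv in ordered[1:]:
        if iv.chrom == cur.chrom and iv.start - cur.end <= max_gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            merged.append(cur)
            cur = iv
    merged.append(cur)
    return merged


def intersect_replicates(
    replicate_peaks: Mapping[str, Sequence[Peak]],
    min_width: int = 1,
    sample_id: Optional[str] = None,
) -> list[ConsensusPeak]:
    """Regions where every replicate of a sample has covering peak signal.

    Computed by a sweep over per-replicate merged coverage: a base belongs
    to a consensus peak iff the number of replicates covering it equals the
    number of replicates.  Maximal such runs at least ``min_width`` wide are
    returned, each carrying the contributing peaks of every replicate and
    height = min over replicates of the max contributing peak height.
    """
    if not replicate_peaks:
        raise ValueError("at least one replicate is required")
    if min_width < 1:
        raise ValueError(f"min_width must be >= 1, got {min_width}")
    n_reps = len(replicate_peaks)
    if sample_id is None:
        for peaks in replicate_peaks.values():
            for p in peaks:
                if p.sample_id is not None:
                    sample_id = p.sample_id
                    break
            if sample_id is not None:
                break

    # Event sweep over per-replicate merged coverage (each replicate
    # contributes depth at most 1 per base regardless of nested peaks).
    events: dict = {}  # chrom -> list of (pos, delta)
    for rep_id, peaks in replicate_peaks.items():
        for iv in merge_intervals([p.interval for p in peaks]):
            events.setdefault(iv.chrom, []).append((iv.start, 1))
            events[iv.chrom].append((iv.end, -1))

    regions: list[GenomicInterval] = []
    for chrom in sorted(events):
        depth = 0
        run_start: Optional[int] = None
        for pos, delta in sorted(events[chrom]):
            if depth == n_reps and run_start is not None and pos > run_start:
                regions.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
            depth += delta
            if depth == n_reps:
                run_start = pos
        # depth returns to 0 at the last event, so no open run remains

    # Adjacent runs split only by bookkeeping events re-merge.
    regions = merge_intervals(regions)
    regions = [iv for iv in regions if iv.width >= min_width]

    consensus: list[ConsensusPeak] = []
    prefix = f"{sample_id}_" if sample_id else ""
    for i, iv in enumerate(regions, start=1):
        support = {}
        heights = []
        for rep_id in sorted(replicate_peaks):
            contributing = tuple(
                p for p in replicate_peaks[rep_id] if p.interval.overlaps(iv)
            )
            support[rep_id] = contributing
            heights.append(max(p.height for p in contributing))
        consensus.append(
            ConsensusPeak(
                peak_id=f"{prefix}cons_{i:05d}",
                interval=iv,
                support=support,
                height=min(heights),
                sample_id=sample_id,
            )
        )
    return consensus


def peak_width_summary(
    peaks: Sequence[Union[Peak, ConsensusPeak]],
    bins: Optional[Sequence[int]] = None,
) -> dict:
    """Histogram of peak widths plus the fraction narrower than 500 bp."""
    if not peaks:
        raise ValueError("peak list is empty")
    widths = np.array([p.width for p in peaks])
    if bins is None:
        top = max(1001, int(widths.max()) + 1)
        bins = [0, 100, 200, 500, 1000, top]
    edges = np.asarray(bins)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(widths, bins=edges)
    return {
        "bin_edges": [int(e) for e in edges],
        "counts": [int(c) for c in counts],
        "n_peaks": int(len(widths)),
        "fraction_below_500": float(np.mean(widths < 500)),
        "median_width": float(np.median(widths)),
    }


def pileup_call(
    fragments: Sequence[GenomicInterval],
    genome_lengths: Mapping[str, int],
    background_rate: float,
    q_cutoff: float = 0.05,
    max_gap: int = 50,
    min_width: int = 50,
) -> list[Peak]:
    """Call peaks from fragment intervals by per-base Poisson enrichment.

    Per-base coverage is compared with a Poisson background of mean
    ``background_rate × mean fragment length`` (expected pileup depth under
    uniform fragment placement).  Upper-tail p-values are BH-adjusted over
    all genome bases; bases with adjusted value < ``q_cutoff`` are merged
    (gaps ≤ ``max_gap`` closed) and runs ≥ ``min_width`` reported as peaks
    with height = max coverage and summit at the leftmost maximal base.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    if any(length <= 0 for length in genome_lengths.values()):
        raise ValueError("zero-length chromosome in genome")
    if not fragments:
        return []
    for frag in fragments:
        if frag.chrom not in genome_lengths:
            raise ValueError(f"fragment on unknown chromosome {frag.chrom!r}")
        if frag.end > genome_lengths[frag.chrom]:
            raise ValueError(
                f"fragment {frag.chrom}:{frag.start}-{frag.end} beyond "
                f"chromosome end {genome_lengths[frag.chrom]}"
            )

    mean_frag_len = float(np.mean([f.width for f in fragments]))
    lam = background_rate * mean_frag_len

    coverage: dict = {}
    for chrom, length in genome_lengths.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        coverage[chrom] = diff
    for frag in fragments:
        coverage[frag.chrom][frag.start] += 1
        coverage[frag.chrom][frag.end] -= 1
    for chrom in coverage:
        coverage[chrom] = np.cumsum(coverage[chrom][:-1])

    # BH over every base of the genome; identical coverage values share a
    # p-value, so adjust on the unique values to stay cheap.
    chroms = sorted(coverage)
    all_cov = np.concatenate([coverage[c] for c in chroms])
    unique_cov, inverse, counts = np.unique(
        all_cov, return_inverse=True, return_counts=True
    )
    pvals_unique = stats.poisson.sf(unique_cov - 1, lam)
    # expand BH by value multiplicity: rank of a base = number of bases with
    # p <= its p; since p decreases with coverage, cumulative counts from the
    # highest coverage down give the ranks.
    m = all_cov.size
    order = np.argsort(pvals_unique)
    ranks_for_unique = np.empty_like(counts)
    ranks_for_unique[order] = np.cumsum(counts[order])
    q_unique = pvals_unique * m / ranks_for_unique
    # enforce step-up monotonicity along increasing p
    q_sorted = np.minimum.accumulate(q_unique[order][::-1])[::-1]
    q_unique[order] = np.minimum(q_sorted, 1.0)
    significant = q_unique[inverse] < q_cutoff

    peaks: list[Peak] = []
    offset = 0
    for chrom in chroms:
        length = genome_lengths[chrom]
        sig = significant[offset : offset + length]
        offset += length
        if not sig.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], sig.view(np.int8), [0]))))
        runs = [
            GenomicInterval(chrom, int(s), int(e))
            for s, e in zip(edges[::2], edges[1::2])
        ]
        for iv in merge_intervals(runs, max_gap=max_gap):
            if iv.width < min_width:
                continue
            cov = coverage[chrom][iv.start : iv.end]
            argmax = int(np.argmax(cov))  # leftmost maximum
            peaks.append(
                Peak(
                    interval=iv,
                    height=float(cov[argmax]),
                    summit_offset=argmax,
                )
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks
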
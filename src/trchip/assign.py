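"""Peak-to-gene assignment via gene-body-plus-flank windows.

A consensus peak is assigned to a gene when it overlaps, by at least one
base, the gene body (introns included) extended by a flank (default 5 kb)
on both sides.  The extension is symmetric and strand-independent.  A peak
overlapping several gene windows is assigned to all of them; a peak
overlapping none is "not annotated".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from intervaltree import IntervalTree

from .consensus import ConsensusPeak
from .io import GeneModel, GenomicInterval, Peak

__all__ = [
    "AssignmentWindow",
    "PeakGeneAssignment",
    "build_windows",
    "assign_peaks",
    "bound_gene_set",
    "classify_peak_locations",
]

DEFAULT_FLANK = 5000


@dataclass(frozen=True)
class AssignmentWindow:
    """A gene body extended by ``flank`` bases on each side."""

    gene_id: str
    interval: GenomicInterval
    flank: int


@dataclass(frozen=True)
class PeakGeneAssignment:
    """Genes whose windows a consensus peak overlaps (possibly none)."""

    consensus_peak_id: str
    gene_ids: frozenset
    category: str  # "genic_or_flank" | "not_annotated"

    def __post_init__(self) -> None:
        expected = "not_annotated" if not self.gene_ids else "genic_or_flank"
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with "
                f"{len(self.gene_ids)} assigned genes"
            )


def build_windows(
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[AssignmentWindow]:
    """One window per gene: body ± flank, clipped at 0 and chromosome end."""
    if flank < 0:
        raise ValueError(f"flank must be non-negative, got {flank}")
    windows = []
    for gene in genes:
        chrom = gene.interval.chrom
        start = max(0, gene.interval.start - flank)
        end = gene.interval.end + flank
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(
                    f"gene {gene.gene_id} on unknown chromosome {chrom!r}"
                )
            end = min(end, chrom_sizes[chrom])
        windows.append(
            AssignmentWindow(
                gene_id=gene.gene_id,
                interval=GenomicInterval(chrom, start, end),
                flank=flank,
            )
        )
    return windows


def _interval_of(peak: Union[Peak, ConsensusPeak, GenomicInterval]) -> GenomicInterval:
    return peak if isinstance(peak, GenomicInterval) else peak.interval


def _id_of(peak, index: int) -> str:
    if isinstance(peak, ConsensusPeak):
        return peak.peak_id
    if isinstance(peak, Peak) and peak.name:
        return peak.name
    return f"peak_{index + 1:05d}"


def _build_trees(windows: Sequence[AssignmentWindow]) -> dict:
    trees: dict = {}
    for w in windows:
        trees.setdefault(w.interval.chrom, IntervalTree()).addi(
            w.interval.start, w.interval.end, w.gene_id
        )
    return trees


def assign_peaks(
    peaks: Sequence[Union[ConsensusPeak, Peak]],
    windows: Sequence[AssignmentWindow],
) -> list[PeakGeneAssignment]:
    """Assign every peak to all gene windows it overlaps by ≥ 1 base."""
    trees = _build_trees(windows)
    assignments = []
    for i, peak in enumerate(peaks):
        iv = _interval_of(peak)
        hits = trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
        gene_ids = frozenset(h.data for h in hits)
        assignments.append(
            PeakGeneAssignment(
                consensus_peak_id=_id_of(peak, i),
                gene_ids=gene_ids,
                category="genic_or_flank" if gene_ids else "not_annotated",
            )
        )
    return assignments


def bound_gene_set(assignments: Sequence[PeakGeneAssignment]) -> set:
    """Genes with at least one peak in their body-plus-flank window."""
    bound: set = set()
    for a in assignments:
        bound |= a.gene_ids
    return bound


def classify_peak_locations(
    peaks: Sequence[Union[ConsensusPeak, Peak, GenomicInterval]],
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> tuple[list[str], dict]:
    """Label each peak gene_body / flank_only / intergenic (body wins).

    Returns the per-peak labels (input order) and summary counts.
    """
    body_trees = _build_trees(
        [AssignmentWindow(g.gene_id, g.interval, 0) for g in genes]
    )
    window_trees = _build_trees(build_windows(genes, flank=flank))
    labels = []
    for peak in peaks:
        iv = _interval_of(peak)
        if body_trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            labels.append("gene_body")
        elif window_trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            labels.append("flank_only")
        else:
            labels.append("intergenic")
    summary = {
        "gene_body": labels.count("gene_body"),
        "flank_only": labels.count("flank_only"),
        "intergenic": labels.count("intergenic"),
    }
    return labels, summary
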
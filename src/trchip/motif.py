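"""DR4 thyroid-hormone response-element scanning.

The canonical TR-RXR binding element is a direct repeat of two (A/G)GGTCA
half-sites separated by four unconstrained spacer bases (DR4).  The scanner
matches a degenerate IUPAC half-site pattern (default ``RGGTCA``) twice at
the configured spacing, on both strands, with an optional per-half-site
mismatch allowance counted only at non-degenerate pattern positions.

Only the direct-repeat geometry is scanned; everted and inverted repeats
(palindromic elements) are out of scope.  Overlapping and nested hits are
all reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .consensus import ConsensusPeak
from .io import GenomicInterval

__all__ = [
    "HalfSiteModel",
    "MotifHit",
    "reverse_complement",
    "scan_dr4",
    "count_tres_in_peaks",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement with full IUPAC support (R↔Y, K↔M, ...)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from None


@dataclass(frozen=True)
class HalfSiteModel:
    """One half-site of the direct repeat, as a degenerate IUPAC pattern.

    ``max_mismatch`` mismatches are tolerated per half-site, counted only
    at non-degenerate (A/C/G/T) pattern positions; an ``N`` in the scanned
    sequence never satisfies a non-N pattern base.
    """

    pattern: str = "RGGTCA"
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("half-site pattern must be non-empty")
        bad = set(self.pattern.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in pattern")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def mismatches(self, window: str) -> int:
        """Mismatch count vs the pattern, or a large value on hard failure.

        Degenerate pattern positions must match (no mismatch budget there);
        fixed positions count toward the budget.
        """
        count = 0
        for pat, base in zip(self.pattern, window):
            allowed = _IUPAC[pat]
            if base in allowed:
                continue
            if len(allowed) == 1:  # fixed position: spend budget
                count += 1
            else:  # degenerate position must match outright
                return len(self.pattern) + 1
        return count


@dataclass(frozen=True)
class MotifHit:
    """One DR4 occurrence; ``start`` is the leftmost base in + coordinates."""

    chrom: str
    start: int
    strand: str
    spacer: int
    half1_seq: str
    half2_seq: str
    mismatches: int

    @property
    def span(self) -> int:
        return 2 * len(self.half1_seq) + self.spacer

    @property
    def end(self) -> int:
        return self.start + self.span


def _scan_plus(
    seq: str, model: HalfSiteModel, spacer: int, chrom: str, strand: str
) -> list[tuple[int, MotifHit]]:
    """Scan one strand; returns (motif-frame offset, hit in that frame)."""
    plen = len(model.pattern)
    span = 2 * plen + spacer
    hits = []
    for i in range(len(seq) - span + 1):
        half1 = seq[i : i + plen]
        mm1 = model.mismatches(half1)
        if mm1 > model.max_mismatch:
            continue
        half2 = seq[i + plen + spacer : i + span]
        mm2 = model.mismatches(half2)
        if mm2 > model.max_mismatch:
            continue
        hits.append(
            (
                i,
                MotifHit(
                    chrom=chrom,
                    start=i,  # re-mapped by the caller for the minus strand
                    strand=strand,
                    spacer=spacer,
                    half1_seq=half1,
                    half2_seq=half2,
                    mismatches=mm1 + mm2,
                ),
            )
        )
    return hits


def scan_dr4(
    seq: str,
    model: HalfSiteModel = HalfSiteModel(),
    spacer: int = 4,
    both_strands: bool = True,
    chrom: str = "seq",
) -> list[MotifHit]:
    """All DR4 occurrences in ``seq``: half-site, spacer, half-site.

    Minus-strand hits are reported at the plus-strand coordinate of their
    leftmost base.  Hits are ordered by (position, strand) with ``+``
    before ``-``; overlapping hits are all reported.
    """
    if spacer < 0:
        raise ValueError(f"spacer must be non-negative, got {spacer}")
    seq = seq.upper()
    span = 2 * len(model.pattern) + spacer
    hits: list[MotifHit] = []
    for offset, hit in _scan_plus(seq, model, spacer, chrom, "+"):
        hits.append(hit)
    if both_strands:
        rc = reverse_complement(seq)
        for offset, hit in _scan_plus(rc, model, spacer, chrom, "-"):
            plus_start = len(seq) - offset - span
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=plus_start,
                    strand="-",
                    spacer=spacer,
                    half1_seq=hit.half1_seq,
                    half2_seq=hit.half2_seq,
                    mismatches=hit.mismatches,
                )
            )
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits


def count_tres_in_peaks(
    peaks: Sequence[Union[ConsensusPeak, GenomicInterval]],
    genome: Mapping[str, str],
    model: HalfSiteModel = HalfSiteModel(),
    spacer: int = 4,
    both_strands: bool = True,
) -> tuple[list[tuple[str, int, list[MotifHit]]], int]:
    """Per-peak DR4 hits in genomic coordinates, plus the grand total.

    Returns ``([(peak_id, count, hits), ...], total)`` in peak input order;
    hit coordinates are shifted into the genomic frame.
    """
    results = []
    total = 0
    for i, peak in enumerate(peaks):
        iv = peak if isinstance(peak, GenomicInterval) else peak.interval
        peak_id = (
            peak.peak_id if isinstance(peak, ConsensusPeak) else f"region_{i + 1}"
        )
        if iv.chrom not in genome:
            raise ValueError(f"peak chromosome {iv.chrom!r} absent from genome")
        seq = genome[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} beyond sequence "
                f"end {len(seq)}"
            )
        local = scan_dr4(
            seq[iv.start : iv.end], model, spacer, both_strands, chrom=iv.chrom
        )
        shifted = [
            MotifHit(
                chrom=h.chrom,
                start=h.start + iv.start,
                strand=h.strand,
                spacer=h.spacer,
                half1_seq=h.half1_seq,
                half2_seq=h.half2_seq,
                mismatches=h.mismatches,
            )
            for h in local
        ]
        results.append((peak_id, len(shifted), shifted))
        total += len(shifted)
    return results, total
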